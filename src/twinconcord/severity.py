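"""Twin-difference distributions, twin-twin correlations and familiality,
and the severity-vs-difference and age-vs-difference associations.

Familiality — the fraction of trait variance attributable to family-level
(genetic plus shared-environment) factors — is reported as the squared
twin correlation, expressed as an integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import AnalysisConfig, Cohort, logger
from .concordance import round_half_up

MEASURES = ("SRS_total", "SCI", "RRB", "ADOS")
_MEASURE_COLUMNS = {
    "SRS_total": ("score_t1", "score_t2"),
    "SCI": ("sci_t1", "sci_t2"),
    "RRB": ("rrb_t1", "rrb_t2"),
    "ADOS": ("ados_t1", "ados_t2"),
}
METHODS = ("pearson", "spearman", "icc_double_entry")


def _measure_arrays(cohort: Cohort, measure: str,
                    config: AnalysisConfig | None = None,
                    scale: str = "T") -> tuple[np.ndarray, np.ndarray]:
    """Per-twin score vectors for a measure, complete pairs only.

    ``scale`` only applies to SRS_total ("raw" converts via the affine map,
    deriving raw from T where the raw column is absent)."""
    if measure not in _MEASURE_COLUMNS:
        raise ValueError(f"unknown measure {measure!r}; one of {MEASURES}")
    if measure == "SRS_total" and scale == "raw":
        config = config or AnalysisConfig()
        vals = [p.raw_scores(config) for p in cohort]
        x = np.array([v[0] for v in vals], dtype=float)
        y = np.array([v[1] for v in vals], dtype=float)
        return x, y
    c1, c2 = _MEASURE_COLUMNS[measure]
    xs, ys = [], []
    dropped = 0
    for p in cohort:
        v1, v2 = getattr(p, c1), getattr(p, c2)
        if v1 is None or v2 is None or v1 != v1 or v2 != v2:
            dropped += 1
            continue
        xs.append(float(v1))
        ys.append(float(v2))
    if dropped:
        logger.info("%s: dropped %d incomplete pairs of %d",
                    measure, dropped, len(cohort))
    return np.asarray(xs), np.asarray(ys)


@dataclass
class DifferenceSummary:
    """Mean and SD of absolute twin-twin differences, plus a histogram."""

    scale: str
    n_pairs: int
    mean_absdiff: float
    sd_absdiff: float
    bin_edges: np.ndarray = field(repr=False)
    bin_density: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"scale": self.scale, "n_pairs": self.n_pairs,
                "mean_absdiff": self.mean_absdiff,
                "sd_absdiff": self.sd_absdiff}


def difference_summary(cohort: Cohort, scale: str = "raw",
                       config: AnalysisConfig | None = None,
                       bin_width: float = 5.0) -> DifferenceSummary:
    """Distribution of |score_1 - score_2| on the chosen scale.

    SD uses the n-1 denominator; the histogram is a density over bins of
    ``bin_width`` score points from zero."""
    if scale not in ("raw", "T"):
        raise ValueError("scale must be 'raw' or 'T'")
    x, y = _measure_arrays(cohort, "SRS_total", config, scale=scale)
    if x.size < 2:
        raise ValueError(f"need >= 2 complete pairs, got {x.size}")
    absdiff = np.abs(x - y)
    edges = np.arange(0.0, absdiff.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    density, edges = np.histogram(absdiff, bins=edges, density=True)
    return DifferenceSummary(
        scale=scale, n_pairs=int(x.size),
        mean_absdiff=float(absdiff.mean()),
        sd_absdiff=float(absdiff.std(ddof=1)),
        bin_edges=edges, bin_density=density,
    )


@dataclass
class CorrelationResult:
    """A twin-twin correlation with its familiality variance share."""

    measure: str
    method: str
    r: float
    r2_percent: int
    n_pairs: int
    p_value: Optional[float] = None

    def to_dict(self) -> dict:
        return {"measure": self.measure, "method": self.method, "r": self.r,
                "r2_percent": self.r2_percent, "n_pairs": self.n_pairs,
                "p_value": self.p_value}


def familiality_variance(r: float) -> int:
    """Percent of variance attributable to familiality: round(100 * r^2).

    Half-up rounding to an integer percent; the sign of r is discarded."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return int(round_half_up(100.0 * r * r, 0))


def twin_correlation(cohort: Cohort, measure: str = "SRS_total",
                     method: str = "pearson",
                     config: AnalysisConfig | None = None,
                     scale: str = "T") -> CorrelationResult:
    """Twin-1 vs twin-2 correlation for one measure.

    ``pearson`` and ``spearman`` use the input twin ordering; the
    ``icc_double_entry`` intraclass method enters every pair twice in both
    orders and is therefore invariant to within-pair ordering (its p-value
    is not reported: the doubled rows are not independent).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; one of {METHODS}")
    x, y = _measure_arrays(cohort, measure, config, scale=scale)
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs for a correlation, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance in a twin column")
    p_value: Optional[float]
    if method == "pearson":
        r, p_value = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p_value = stats.spearmanr(x, y)
    else:
        xx = np.concatenate([x, y])
        yy = np.concatenate([y, x])
        r = float(np.corrcoef(xx, yy)[0, 1])
        p_value = None
    r = float(r)
    if method != "icc_double_entry":
        de = twin_correlation(cohort, measure, "icc_double_entry", config, scale)
        if abs(de.r - r) > 0.05:
            logger.info("%s %s r=%.3f differs from double-entry ICC %.3f by "
                        "> 0.05 (ordering-sensitive)", measure, method, r, de.r)
    return CorrelationResult(measure=measure, method=method, r=r,
                             r2_percent=familiality_variance(r),
                             n_pairs=int(x.size),
                             p_value=None if p_value is None else float(p_value))


def severity_difference_association(cohort: Cohort,
                                    config: AnalysisConfig | None = None,
                                    scale: str = "T") -> dict:
    """Spearman association between a pair's mean score and its |difference|.

    A positive rho indicates that twin-twin differences grow with pair
    severity — the signature of severity-dependent non-shared influence."""
    x, y = _measure_arrays(cohort, "SRS_total", config, scale=scale)
    if x.size < 5:
        raise ValueError(f"need >= 5 complete pairs, got {x.size}")
    mean = (x + y) / 2.0
    absdiff = np.abs(x - y)
    if np.unique(mean).size == 1 or np.unique(absdiff).size == 1:
        raise ValueError("undefined association: all-tied ranks")
    rho, p = stats.spearmanr(mean, absdiff)
    return {"rho": float(rho), "p_value": float(p), "n_pairs": int(x.size)}


def age_association(cohort: Cohort, config: AnalysisConfig | None = None,
                    scale: str = "T") -> dict:
    """Pearson and Spearman correlations of pair age with |difference|."""
    pairs = [p for p in cohort if p.age is not None]
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 pairs with ages, got {len(pairs)}")
    sub = Cohort(label=cohort.label, pairs=pairs, provenance=cohort.provenance)
    x, y = _measure_arrays(sub, "SRS_total", config, scale=scale)
    age = np.array([p.age for p in pairs], dtype=float)
    absdiff = np.abs(x - y)
    if np.std(age) == 0 or np.std(absdiff) == 0:
        raise ValueError("undefined correlation: constant ages or differences")
    r, _ = stats.pearsonr(age, absdiff)
    rho, _ = stats.spearmanr(age, absdiff)
    return {"pearson_r": float(r), "spearman_rho": float(rho),
            "n_pairs": int(age.size)}
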