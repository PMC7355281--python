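"""Domain types, CSV input/output, validation, and raw/T score conversion.

The atomic record is a monozygotic twin pair measured on the Social
Responsiveness Scale (SRS-2): each twin has a norm-referenced total T-score
(population mean 50, SD 10), optionally the underlying raw score (0-195),
optional SCI (social communication and interaction) and RRB (restricted
interests and repetitive behaviors) subdomain T-scores, an optional ADOS
social-affect score from clinician observation, and an optional
parent-reported diagnosis flag.

Raw and T scales are linked by a single configurable affine map; every
correlation computed downstream is invariant to which scale is used.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("twinconcord")

SEXES = ("MM", "FF", "unknown")
COHORT_LABELS = ("epidemiologic", "IAN", "AGRE", "other")

#: Canonical CSV column order (wide format: one row per pair).
CSV_COLUMNS = [
    "pair_id", "cohort", "sex", "age",
    "score_t1", "score_t2", "raw_t1", "raw_t2",
    "sci_t1", "sci_t2", "rrb_t1", "rrb_t2",
    "ados_t1", "ados_t2", "dx_t1", "dx_t2",
]
REQUIRED_COLUMNS = ["pair_id", "cohort", "score_t1", "score_t2"]


class SchemaError(ValueError):
    """The input file violates the expected column schema."""


class RowError(ValueError):
    """A single data row failed validation; carries the 1-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row
        self.message = message


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants shared by every stage.

    Parameters
    ----------
    clinical_threshold
        T-score cutoff for clinical-level affectation (65T, i.e. 1.5
        population SDs above the general-population mean).
    subthreshold_floor
        Lower edge of the subthreshold band used by the straddle analysis
        (50T, the population mean).
    discordance_sd
        The clinical-population SD of SRS T-scores used as the unit of the
        quantitative discordance criterion (default 18.1 T-points).
    discordance_multiplier
        k in the magnitude criterion |t1 - t2| >= k * discordance_sd.
        The discordance classifier defaults to k = 1.5; the reported-
        discordance correction procedure uses k = 1.0.
    raw_to_t_slope, raw_to_t_intercept
        Affine map T = slope * raw + intercept. The defaults (0.55, 25.0)
        jointly reconcile the printed raw-scale difference summaries with
        the printed T-score means/SDs and twin correlations; the published
        sex-specific SRS-2 norm tables are not reproduced.
    """

    clinical_threshold: float = 65.0
    subthreshold_floor: float = 50.0
    discordance_sd: float = 18.1
    discordance_multiplier: float = 1.5
    raw_to_t_slope: float = 0.55
    raw_to_t_intercept: float = 25.0
    seed: int = 20191218
    t_range: tuple[float, float] = (30.0, 130.0)
    raw_range: tuple[float, float] = (0.0, 195.0)
    age_range: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self) -> None:
        if not self.clinical_threshold > self.subthreshold_floor:
            raise ValueError("clinical_threshold must exceed subthreshold_floor")
        if self.discordance_sd <= 0:
            raise ValueError("discordance_sd must be positive")
        if self.discordance_multiplier <= 0:
            raise ValueError("discordance_multiplier must be positive")
        if self.raw_to_t_slope <= 0:
            raise ValueError("raw_to_t_slope must be positive")

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key-value config file (YAML or JSON)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError(f"config file {path} is not a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("t_range", "raw_range", "age_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        for key in ("t_range", "raw_range", "age_range"):
            d[key] = list(d[key])
        return d


def raw_to_t(raw: float, config: AnalysisConfig) -> float:
    """Convert an SRS raw score to a T-score via the configured affine map."""
    lo, hi = config.raw_range
    if not (lo <= raw <= hi):
        raise ValueError(f"raw score {raw} outside valid range [{lo}, {hi}]")
    return config.raw_to_t_slope * raw + config.raw_to_t_intercept


def t_to_raw(t: float, config: AnalysisConfig) -> float:
    """Invert the affine raw->T map exactly."""
    return (t - config.raw_to_t_intercept) / config.raw_to_t_slope


@dataclass(frozen=True)
class TwinPair:
    """One monozygotic twin pair's scores and metadata.

    Twin order within a pair is preserved as given in the input; every
    statistic downstream is either order-symmetric or offers an
    order-free variant (double-entry ICC).
    """

    pair_id: str
    cohort: str = "other"
    sex: str = "unknown"
    age: Optional[float] = None
    score_t1: float = math.nan
    score_t2: float = math.nan
    raw_t1: Optional[float] = None
    raw_t2: Optional[float] = None
    sci_t1: Optional[float] = None
    sci_t2: Optional[float] = None
    rrb_t1: Optional[float] = None
    rrb_t2: Optional[float] = None
    ados_t1: Optional[float] = None
    ados_t2: Optional[float] = None
    dx_t1: Optional[bool] = None
    dx_t2: Optional[bool] = None

    def validate(self, config: AnalysisConfig) -> None:
        """Raise ValueError on any invariant violation."""
        if not self.pair_id:
            raise ValueError("pair_id must be non-empty")
        if self.cohort not in COHORT_LABELS:
            raise ValueError(f"unknown cohort label {self.cohort!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex code {self.sex!r}")
        tlo, thi = config.t_range
        for name in ("score_t1", "score_t2", "sci_t1", "sci_t2", "rrb_t1", "rrb_t2"):
            v = getattr(self, name)
            if v is None:
                continue
            if math.isnan(v):
                if name in ("score_t1", "score_t2"):
                    raise ValueError(f"{name} is required")
                continue
            if not (tlo <= v <= thi):
                raise ValueError(f"{name}={v} outside T range [{tlo}, {thi}]")
        rlo, rhi = config.raw_range
        for name in ("raw_t1", "raw_t2"):
            v = getattr(self, name)
            if v is not None and not (rlo <= v <= rhi):
                raise ValueError(f"{name}={v} outside raw range [{rlo}, {rhi}]")
        if self.age is not None:
            alo, ahi = config.age_range
            if not (alo <= self.age <= ahi):
                raise ValueError(f"age={self.age} outside range [{alo}, {ahi}]")
        # raw and T, when both present, must agree with the affine map to
        # within 1 T-point (rounding slack of published score tables).
        for raw, t, side in ((self.raw_t1, self.score_t1, 1), (self.raw_t2, self.score_t2, 2)):
            if raw is not None and not math.isnan(t):
                implied = config.raw_to_t_slope * raw + config.raw_to_t_intercept
                if abs(implied - t) > 1.0:
                    raise ValueError(
                        f"twin {side}: raw {raw} implies {implied:.2f}T, "
                        f"recorded {t}T (> 1 T-point apart)"
                    )

    def raw_scores(self, config: AnalysisConfig) -> tuple[float, float]:
        """Raw scores for both twins, derived from T-scores when absent."""
        r1 = self.raw_t1 if self.raw_t1 is not None else t_to_raw(self.score_t1, config)
        r2 = self.raw_t2 if self.raw_t2 is not None else t_to_raw(self.score_t2, config)
        return r1, r2


@dataclass
class Cohort:
    """An ordered collection of twin pairs with provenance."""

    label: str
    pairs: list[TwinPair] = field(default_factory=list)
    provenance: str = "observed"  # observed | synthetic
    seed: Optional[int] = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pair_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[TwinPair]:
        return iter(self.pairs)

    def require_nonempty(self) -> None:
        if not self.pairs:
            raise ValueError(f"cohort {self.label!r} is empty")

    def to_frame(self) -> pd.DataFrame:
        """Wide-format DataFrame in the canonical column order."""
        rows = []
        for p in self.pairs:
            row = {c: getattr(p, c) for c in CSV_COLUMNS}
            for dx in ("dx_t1", "dx_t2"):
                v = row[dx]
                row[dx] = None if v is None else ("yes" if v else "no")
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_optional_float(value, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unparseable numeric value {value!r} in column {column}")


def _parse_dx(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    s = str(value).strip().lower()
    if s in ("yes", "true", "1", "1.0"):
        return True
    if s in ("no", "false", "0", "0.0"):
        return False
    if s == "unknown":
        return None
    raise ValueError(f"unparseable diagnosis flag {value!r}")


def read_cohort(path: str | Path, config: AnalysisConfig | None = None,
                label: str | None = None) -> Cohort:
    """Read a wide-format twin-pair CSV.

    One row per pair; empty cells are missing values (never zeros). Rows
    failing validation are rejected with row-numbered diagnostics collected
    on the returned cohort and logged; accepted + rejected = total rows.
    """
    config = config or AnalysisConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    pairs: list[TwinPair] = []
    diagnostics: list[str] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            pairs.append(_pair_from_record(rec, config))
        except ValueError as exc:
            diagnostics.append(f"row {i}: {exc}")
    label = label or (pairs[0].cohort if pairs else path.stem)
    cohort = Cohort(label=label, pairs=pairs, provenance="observed",
                    diagnostics=diagnostics)
    logger.info("read_cohort(%s): %d accepted, %d rejected",
                path, len(pairs), len(diagnostics))
    for d in diagnostics:
        logger.warning("read_cohort(%s): %s", path, d)
    return cohort


def _pair_from_record(rec: dict, config: AnalysisConfig) -> TwinPair:
    def opt(col):
        return _parse_optional_float(rec.get(col), col)

    score_t1 = opt("score_t1")
    score_t2 = opt("score_t2")
    if score_t1 is None or score_t2 is None:
        raise ValueError("score_t1 and score_t2 are required")
    pair = TwinPair(
        pair_id=str(rec.get("pair_id", "")).strip(),
        cohort=str(rec.get("cohort", "other")).strip() or "other",
        sex=str(rec.get("sex", "") or "unknown").strip() or "unknown",
        age=opt("age"),
        score_t1=score_t1, score_t2=score_t2,
        raw_t1=opt("raw_t1"), raw_t2=opt("raw_t2"),
        sci_t1=opt("sci_t1"), sci_t2=opt("sci_t2"),
        rrb_t1=opt("rrb_t1"), rrb_t2=opt("rrb_t2"),
        ados_t1=opt("ados_t1"), ados_t2=opt("ados_t2"),
        dx_t1=_parse_dx(rec.get("dx_t1")), dx_t2=_parse_dx(rec.get("dx_t2")),
    )
    pair.validate(config)
    return pair


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with deterministic column order.

    Full float precision (repr round-trip); absent optionals become empty
    cells so that read_cohort(write_cohort(c)) == c field-for-field.
    """
    cohort.require_nonempty()
    df = cohort.to_frame()
    df.to_csv(Path(path), index=False, na_rep="", float_format=None)
    logger.info("write_cohort(%s): wrote %d pairs", path, len(cohort))


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    """Pair-for-pair equality of scores and metadata (not provenance)."""
    if len(a) != len(b):
        return False
    for pa, pb in zip(a, b):
        for col in CSV_COLUMNS:
            va, vb = getattr(pa, col), getattr(pb, col)
            if isinstance(va, float) and isinstance(vb, float):
                if not (math.isclose(va, vb, rel_tol=0, abs_tol=1e-12)
                        or (math.isnan(va) and math.isnan(vb))):
                    return False
            elif va != vb:
                return False
    return True


def config_snapshot(config: AnalysisConfig) -> str:
    """Stable JSON snapshot of a config, for report provenance."""
    return json.dumps(config.to_dict(), sort_keys=True)
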