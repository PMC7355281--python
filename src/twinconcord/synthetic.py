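"""Synthetic monozygotic-twin cohort generator.

The generating model decomposes each pair's scores, on the raw SRS scale,
into a shared pair-level severity mu (familial: genetic plus shared
environment) and a within-pair difference d (non-shared environment plus
measurement error):

    raw_1 = mu + d/2,    raw_2 = mu - d/2,
    mu ~ N(mean_severity, sd_severity^2),   d ~ N(0, sd_diff^2),

with mu and d independent. Under this model

    E|d|          = sd_diff * sqrt(2/pi)
    corr(t1, t2)  = (sd_severity^2 - sd_diff^2/4) / (sd_severity^2 + sd_diff^2/4)

which inverts in closed form, so the generator can be calibrated exactly to
a target twin correlation and a target mean absolute difference
(``calibrate_generator``).

A severity-dependent discordance-variance regime is supported: pairs whose
latent mean severity lies at or above the clinical threshold (on the T
scale) draw d with an amplified SD ``sd_diff_above`` >= ``sd_diff_below``.
The regime is keyed on the latent mu, not on observed scores, so that
classification tests on generated data are not circular. By default
calibration sets both SDs equal (no regime effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import AnalysisConfig, Cohort, TwinPair, logger, t_to_raw

SQRT_HALF_PI = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Calibrated parameters of the synthetic pair model (raw-score scale)."""

    n_pairs: int
    mean_severity: float
    sd_severity: float
    sd_diff_below: float
    sd_diff_above: float
    target_r: float
    target_mean_absdiff: float
    subscale_r2: dict[str, float] = field(default_factory=dict)
    ados_r: Optional[float] = None
    ados_noise_sd: Optional[float] = None
    seed: int = 20191218

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.sd_severity <= 0 or self.sd_diff_below <= 0 or self.sd_diff_above <= 0:
            raise ValueError("all SDs must be positive")
        if not (0 <= self.target_r < 1):
            raise ValueError("target_r must be in [0, 1)")
        if self.sd_diff_above < self.sd_diff_below:
            raise ValueError("sd_diff_above must be >= sd_diff_below")


@dataclass(frozen=True)
class CohortPreset:
    """Printed summary statistics of one study cohort, as generator targets.

    ``mean_t`` is the cohort mean T-score; ``target_mean_absdiff`` is on the
    raw-score scale; ``subscale_r2`` maps SCI/RRB to the fraction of variance
    attributable to familiality (squared twin correlation).
    """

    name: str
    n_pairs: int
    target_r: float
    target_mean_absdiff: float
    mean_t: float
    sd_t: float
    mm_fraction: float
    age_range: tuple[float, float]
    subscale_r2: dict[str, float] = field(default_factory=dict)
    ados_r: Optional[float] = None
    clinical: bool = False


#: The three study cohorts plus the combined clinical group.
PRESETS: dict[str, CohortPreset] = {
    "epidemiologic": CohortPreset(
        name="epidemiologic", n_pairs=288, target_r=0.754,
        target_mean_absdiff=7.7, mean_t=49.0, sd_t=7.6,
        mm_fraction=105 / 288, age_range=(4.0, 15.0),
        subscale_r2={"SCI": 0.57, "RRB": 0.48},
    ),
    "IAN": CohortPreset(
        name="IAN", n_pairs=23, target_r=0.27,
        target_mean_absdiff=33.0, mean_t=78.0, sd_t=18.5,
        mm_fraction=62 / 78, age_range=(4.0, 18.0),
        subscale_r2={"SCI": 0.06, "RRB": 0.20}, clinical=True,
    ),
    "AGRE": CohortPreset(
        name="AGRE", n_pairs=55, target_r=0.27,
        target_mean_absdiff=33.0, mean_t=78.0, sd_t=18.5,
        mm_fraction=62 / 78, age_range=(4.0, 18.0),
        subscale_r2={"SCI": 0.06, "RRB": 0.20}, ados_r=0.21, clinical=True,
    ),
    "clinical_combined": CohortPreset(
        name="clinical_combined", n_pairs=78, target_r=0.27,
        target_mean_absdiff=33.0, mean_t=78.0, sd_t=18.5,
        mm_fraction=62 / 78, age_range=(4.0, 18.0),
        subscale_r2={"SCI": 0.06, "RRB": 0.20}, ados_r=0.21, clinical=True,
    ),
}


def calibrate_generator(target_r: float, target_mean_absdiff: float,
                        config: AnalysisConfig | None = None, *,
                        n_pairs: int = 1000,
                        mean_t: float = 50.0,
                        subscale_r2: dict[str, float] | None = None,
                        ados_r: float | None = None,
                        amplification: float = 1.0,
                        seed: int | None = None) -> GeneratorParams:
    """Closed-form inversion of the pair-mean/difference model.

        sd_diff     = target_mean_absdiff * sqrt(pi/2)
        sd_severity = sqrt( (sd_diff^2 / 4) * (1 + r) / (1 - r) )

    ``amplification`` sets sd_diff_above / sd_diff_below; at the default 1.0
    the regime is inert and the calibration targets are met exactly in
    expectation. With amplification > 1, sd_diff_below = sd_diff and only
    above-threshold pairs deviate (the overall moments then exceed the
    targets by the above-threshold mass).
    """
    config = config or AnalysisConfig()
    if target_r >= 1:
        raise ValueError("target_r = 1 is degenerate (zero within-pair variance)")
    if target_r < 0:
        raise ValueError("negative twin correlations are not supported")
    if target_mean_absdiff <= 0:
        raise ValueError("target_mean_absdiff must be positive")
    if amplification < 1.0:
        raise ValueError("amplification must be >= 1")
    sd_diff = target_mean_absdiff * SQRT_HALF_PI
    sd_mu = math.sqrt((sd_diff ** 2 / 4.0) * (1 + target_r) / (1 - target_r))
    ados_noise = None
    if ados_r is not None:
        if not (0 < ados_r <= target_r):
            raise ValueError("ados_r must be in (0, target_r]: the ADOS adds "
                             "instrument noise and cannot raise the twin correlation")
        # ADOS = affine(latent severity) + noise; its twin correlation is
        # target_r * reliability, so reliability = ados_r / target_r.
        reliability = ados_r / target_r
        sd_ind = math.sqrt(sd_mu ** 2 + sd_diff ** 2 / 4.0)
        ados_noise = sd_ind * math.sqrt((1 - reliability) / reliability)
    return GeneratorParams(
        n_pairs=n_pairs,
        mean_severity=t_to_raw(mean_t, config),
        sd_severity=sd_mu,
        sd_diff_below=sd_diff,
        sd_diff_above=sd_diff * amplification,
        target_r=target_r,
        target_mean_absdiff=target_mean_absdiff,
        subscale_r2=dict(subscale_r2 or {}),
        ados_r=ados_r,
        ados_noise_sd=ados_noise,
        seed=seed if seed is not None else config.seed,
    )


def params_from_preset(preset: CohortPreset | str,
                       config: AnalysisConfig | None = None, *,
                       n_pairs: int | None = None,
                       amplification: float = 1.0,
                       seed: int | None = None) -> GeneratorParams:
    """Calibrated parameters for one of the named study-cohort presets."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    return calibrate_generator(
        preset.target_r, preset.target_mean_absdiff, config,
        n_pairs=n_pairs if n_pairs is not None else preset.n_pairs,
        mean_t=preset.mean_t, subscale_r2=preset.subscale_r2,
        ados_r=preset.ados_r, amplification=amplification, seed=seed,
    )


def _clamp_raw(raw: np.ndarray, config: AnalysisConfig) -> tuple[np.ndarray, int]:
    """Clamp raw scores to the intersection of the raw and T validity ranges.

    Clamping on the raw scale keeps the affine raw->T relation exact for
    every emitted pair (T is computed from the clamped raw).
    """
    lo = max(config.raw_range[0], t_to_raw(config.t_range[0], config))
    hi = min(config.raw_range[1], t_to_raw(config.t_range[1], config))
    clipped = np.clip(raw, lo, hi)
    return clipped, int(np.sum(clipped != raw))


def generate_cohort(params: GeneratorParams,
                    preset: CohortPreset | str | None = None,
                    config: AnalysisConfig | None = None) -> Cohort:
    """Draw a synthetic cohort from the calibrated pair model.

    Identical (params, seed) gives a bit-identical cohort. Scores are
    clamped to the configured validity ranges; clamping events are logged
    rather than re-drawn so the calibrated moments stay transparent.
    """
    config = config or AnalysisConfig()
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if preset is not None and params.n_pairs != preset.n_pairs:
        raise ValueError(
            f"params.n_pairs={params.n_pairs} does not match preset "
            f"{preset.name!r} (n_pairs={preset.n_pairs}); pass n_pairs "
            "explicitly when overriding a preset")
    rng = np.random.default_rng(params.seed)
    n = params.n_pairs
    slope, icept = config.raw_to_t_slope, config.raw_to_t_intercept

    mu = rng.normal(params.mean_severity, params.sd_severity, size=n)
    mu_t = slope * mu + icept
    above = mu_t >= config.clinical_threshold
    sd_d = np.where(above, params.sd_diff_above, params.sd_diff_below)
    d = rng.normal(0.0, 1.0, size=n) * sd_d
    raw1, n_clamped1 = _clamp_raw(mu + d / 2.0, config)
    raw2, n_clamped2 = _clamp_raw(mu - d / 2.0, config)
    if n_clamped1 + n_clamped2:
        logger.info("generate_cohort: clamped %d of %d scores to validity range",
                    n_clamped1 + n_clamped2, 2 * n)
    t1, t2 = slope * raw1 + icept, slope * raw2 + icept

    # Metadata only: the study found no sex or age effects on differences.
    mm_fraction = preset.mm_fraction if preset is not None else 0.5
    age_lo, age_hi = preset.age_range if preset is not None else (4.0, 18.0)
    sex = np.where(rng.random(n) < mm_fraction, "MM", "FF")
    age = np.round(rng.uniform(age_lo, age_hi, size=n), 1)

    sd_t = preset.sd_t if preset is not None else slope * math.sqrt(
        params.sd_severity ** 2 + params.sd_diff_below ** 2 / 4.0)
    mean_t = preset.mean_t if preset is not None else slope * params.mean_severity + icept
    subscales = {
        name: _subscale_scores(rng, r2, mu, params, mean_t, sd_t, config)
        for name, r2 in params.subscale_r2.items()
    }
    ados = None
    if params.ados_r is not None:
        ados = _ados_scores(rng, params, raw1, raw2)

    clinical = preset.clinical if preset is not None else (
        mean_t >= config.clinical_threshold)
    label = preset.name if preset is not None else "synthetic"
    pairs = []
    for i in range(n):
        sci = subscales.get("SCI")
        rrb = subscales.get("RRB")
        pairs.append(TwinPair(
            pair_id=f"{label}-{i + 1:04d}",
            cohort=preset.name if preset is not None and preset.name in
                   ("epidemiologic", "IAN", "AGRE") else "other",
            sex=str(sex[i]), age=float(age[i]),
            score_t1=float(t1[i]), score_t2=float(t2[i]),
            raw_t1=float(raw1[i]), raw_t2=float(raw2[i]),
            sci_t1=float(sci[0][i]) if sci is not None else None,
            sci_t2=float(sci[1][i]) if sci is not None else None,
            rrb_t1=float(rrb[0][i]) if rrb is not None else None,
            rrb_t2=float(rrb[1][i]) if rrb is not None else None,
            ados_t1=float(ados[0][i]) if ados is not None else None,
            ados_t2=float(ados[1][i]) if ados is not None else None,
            dx_t1=bool(t1[i] >= config.clinical_threshold) if clinical else None,
            dx_t2=bool(t2[i] >= config.clinical_threshold) if clinical else None,
        ))
    return Cohort(label=label, pairs=pairs, provenance="synthetic",
                  seed=params.seed)


def _subscale_scores(rng: np.random.Generator, r2: float, mu: np.ndarray,
                     params: GeneratorParams, mean_t: float, sd_t: float,
                     config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Subscale T-scores with twin correlation sqrt(r2)^2 = r2 variance share.

    Half of the pair-level (shared) variance loads on the total-score latent
    mu, half on a subscale-specific pair factor; the twin-specific residual
    makes up the rest, so corr(s1, s2) = r_sub with r_sub = sqrt(r2).
    """
    n = mu.size
    r_sub = math.sqrt(r2)
    z_mu = (mu - params.mean_severity) / params.sd_severity
    shared = math.sqrt(r_sub / 2.0) * z_mu + math.sqrt(r_sub / 2.0) * rng.standard_normal(n)
    resid_sd = math.sqrt(1.0 - r_sub)
    s1 = mean_t + sd_t * (shared + resid_sd * rng.standard_normal(n))
    s2 = mean_t + sd_t * (shared + resid_sd * rng.standard_normal(n))
    lo, hi = config.t_range
    return np.clip(s1, lo, hi), np.clip(s2, lo, hi)


def _ados_scores(rng: np.random.Generator, params: GeneratorParams,
                 raw1: np.ndarray, raw2: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """ADOS social-affect scores on a 0-20 integer scale.

    Each twin's ADOS is an affine function of their latent SRS severity plus
    independent clinician-instrument noise calibrated (in ``calibrate_
    generator``) so the ADOS twin correlation hits ados_r before rounding.
    """
    sd_ind = math.sqrt(params.sd_severity ** 2 + params.sd_diff_below ** 2 / 4.0)
    b = 4.0 / sd_ind                    # ~4 ADOS points per severity SD
    a = 10.0 - b * params.mean_severity  # center the scale at 10
    noise = params.ados_noise_sd if params.ados_noise_sd is not None else 0.0
    out = []
    for raw in (raw1, raw2):
        scores = a + b * raw + b * rng.normal(0.0, noise, size=raw.size)
        out.append(np.clip(np.round(scores), 0, 20))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Deterministic reclassification fixture
# ---------------------------------------------------------------------------

#: (pair_id, t_low, t_high, reported_discordant). Scores are T-scores.
#: Among the 9 reported-discordant pairs: 3 have the lower twin above the
#: 65T clinical cutoff, 4 have a twin difference under 18.1 with the lower
#: twin below the cutoff, and 2 meet both quantitative discordance
#: conditions (difference >= 18.1 and twins on opposite sides of 65T).
_FIXTURE_ROWS: list[tuple[str, float, float, bool]] = [
    # 14 reported-concordant pairs (both twins diagnosed, both >= 65T)
    ("IANfix-01", 66.0, 70.0, False),
    ("IANfix-02", 68.0, 75.0, False),
    ("IANfix-03", 70.0, 71.0, False),
    ("IANfix-04", 72.0, 90.0, False),
    ("IANfix-05", 74.0, 80.0, False),
    ("IANfix-06", 76.0, 84.0, False),
    ("IANfix-07", 78.0, 101.0, False),
    ("IANfix-08", 80.0, 86.0, False),
    ("IANfix-09", 82.0, 95.0, False),
    ("IANfix-10", 85.0, 88.0, False),
    ("IANfix-11", 90.0, 112.0, False),
    ("IANfix-12", 95.0, 99.0, False),
    ("IANfix-13", 100.0, 120.0, False),
    ("IANfix-14", 105.0, 110.0, False),
    # 3 reported-discordant, lower twin above the cutoff (rule a)
    ("IANfix-15", 68.0, 95.0, True),
    ("IANfix-16", 70.0, 88.0, True),
    ("IANfix-17", 72.0, 110.0, True),
    # 4 reported-discordant, difference < 18.1, lower twin below cutoff (rule b)
    ("IANfix-18", 55.0, 70.0, True),
    ("IANfix-19", 52.0, 66.0, True),
    ("IANfix-20", 60.0, 72.0, True),
    ("IANfix-21", 58.0, 70.0, True),
    # 2 reported-discordant meeting both quantitative discordance conditions
    ("IANfix-22", 45.0, 90.0, True),
    ("IANfix-23", 40.0, 80.0, True),
]


def make_reclassification_fixture(config: AnalysisConfig | None = None) -> Cohort:
    """Deterministic 23-pair IAN-like cohort for the correction procedure.

    Hard-coded scores (seed-independent): 14 pairs reported concordant and 9
    reported discordant, structured so that the quantitative correction at
    k = 1.0 reclassifies 3 + 4 of the 9 and leaves exactly 2 discordant.
    """
    config = config or AnalysisConfig()
    pairs = []
    for pair_id, t_low, t_high, reported_disc in _FIXTURE_ROWS:
        pairs.append(TwinPair(
            pair_id=pair_id, cohort="IAN", sex="MM", age=10.0,
            score_t1=t_high, score_t2=t_low,
            raw_t1=t_to_raw(t_high, config), raw_t2=t_to_raw(t_low, config),
            dx_t1=True, dx_t2=not reported_disc,
        ))
    return Cohort(label="IAN-reclassification-fixture", pairs=pairs,
                  provenance="synthetic", seed=None)
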