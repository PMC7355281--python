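"""Concordance statistics, the quantitative discordance classifier, the
reported-discordance correction, and the threshold-straddle analysis.

Discordance is defined quantitatively: a pair is discordant when
(1) the twin-twin T-score difference is at least k clinical-population
standard deviations (default 1.5 x 18.1T), AND (2) the twins fall on
opposite sides of the clinical severity threshold (65T; a twin exactly at
the threshold counts as affected). Pairs that straddle the threshold but
fail the magnitude criterion are "straddling" — categorically discordant by
the classical definition yet quantitatively similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .data_model import AnalysisConfig, Cohort, TwinPair

LABELS = ("concordant_affected", "concordant_unaffected",
          "discordant", "straddling_subcriterion")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding, for comparison with published 2-dp rates."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PairClass:
    """Classification of a single pair under the quantitative criteria."""

    pair_id: str
    label: str
    lower_score: float
    upper_score: float
    abs_diff_t: float
    meets_magnitude: bool
    straddles_threshold: bool

    def __post_init__(self) -> None:
        assert self.label in LABELS
        assert self.upper_score >= self.lower_score


@dataclass
class ConcordanceResult:
    """Concordant/discordant counts with pairwise and probandwise rates.

    rate_pairwise = C / (C + D); rate_probandwise = 2C / (2C + D). The
    probandwise form counts each concordant pair twice, approximating the
    probability that an affected proband's co-twin is affected under
    complete ascertainment; it is never smaller than the pairwise rate.
    """

    n_concordant: int
    n_discordant: int
    audit: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_concordant < 0 or self.n_discordant < 0:
            raise ValueError("counts must be non-negative")
        if self.n_concordant + self.n_discordant == 0:
            raise ValueError("undefined rate: no classified pairs (C + D = 0)")

    @property
    def n_pairs(self) -> int:
        return self.n_concordant + self.n_discordant

    @property
    def rate_pairwise(self) -> float:
        return self.n_concordant / self.n_pairs

    @property
    def rate_probandwise(self) -> float:
        c, d = self.n_concordant, self.n_discordant
        return 2 * c / (2 * c + d)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "rate_pairwise": self.rate_pairwise,
            "rate_pairwise_2dp": round_half_up(self.rate_pairwise),
            "rate_probandwise": self.rate_probandwise,
            "rate_probandwise_2dp": round_half_up(self.rate_probandwise),
            "audit": self.audit,
        }


def concordance_from_counts(n_concordant: int, n_discordant: int) -> ConcordanceResult:
    """Pairwise and probandwise concordance from raw pair counts."""
    return ConcordanceResult(n_concordant=n_concordant, n_discordant=n_discordant)


def classify_pair(pair: TwinPair, config: AnalysisConfig | None = None) -> PairClass:
    """Apply the two-part quantitative discordance criterion to one pair.

    Symmetric in twin order. The magnitude criterion uses >= (a difference
    exactly at k * discordance_sd meets it); a twin exactly at the clinical
    threshold counts as affected.
    """
    config = config or AnalysisConfig()
    t1, t2 = pair.score_t1, pair.score_t2
    if t1 is None or t2 is None or t1 != t1 or t2 != t2:
        raise ValueError(f"pair {pair.pair_id}: both T-scores are required")
    lower, upper = min(t1, t2), max(t1, t2)
    diff = upper - lower
    thr = config.clinical_threshold
    meets_magnitude = diff >= config.discordance_multiplier * config.discordance_sd
    straddles = lower < thr <= upper
    if meets_magnitude and straddles:
        label = "discordant"
    elif straddles:
        label = "straddling_subcriterion"
    elif lower >= thr:
        label = "concordant_affected"
    else:
        label = "concordant_unaffected"
    return PairClass(pair_id=pair.pair_id, label=label,
                     lower_score=lower, upper_score=upper, abs_diff_t=diff,
                     meets_magnitude=meets_magnitude,
                     straddles_threshold=straddles)


def classify_cohort(cohort: Cohort, config: AnalysisConfig | None = None
                    ) -> list[PairClass]:
    return [classify_pair(p, config) for p in cohort]


def quantitative_concordance(cohort: Cohort, config: AnalysisConfig | None = None
                             ) -> ConcordanceResult:
    """Concordance of a cohort under the quantitative classifier."""
    cohort.require_nonempty()
    classes = classify_cohort(cohort, config)
    d = sum(1 for c in classes if c.label == "discordant")
    return concordance_from_counts(len(classes) - d, d)


def correct_reported_concordance(cohort: Cohort,
                                 config: AnalysisConfig | None = None,
                                 k: float = 1.0) -> ConcordanceResult:
    """Correct parent-reported discordance by the quantitative standards.

    Every reported-discordant pair is reclassified concordant if
    (a) the lower-scoring twin's SRS T-score reaches the clinical cutoff
    (the pair is concordantly affected in quantitative terms), or
    (b) the twin-twin difference is below k * discordance_sd (default one
    full clinical SD, 18.1T). Reported-concordant pairs are never touched.
    The audit trail records each reclassification and the rule that fired.
    """
    config = config or AnalysisConfig()
    cohort.require_nonempty()
    flagged = [p for p in cohort if p.dx_t1 is not None and p.dx_t2 is not None]
    if not flagged:
        raise ValueError(
            "no reported-diagnosis flags in cohort; use classify_pair / "
            "quantitative_concordance for purely score-based classification")
    audit: list[dict] = []
    n_conc = n_disc = 0
    for pair in flagged:
        reported_discordant = pair.dx_t1 != pair.dx_t2
        if not reported_discordant:
            n_conc += 1
            continue
        lower = min(pair.score_t1, pair.score_t2)
        diff = abs(pair.score_t1 - pair.score_t2)
        if lower >= config.clinical_threshold:
            audit.append({"pair_id": pair.pair_id,
                          "rule": "lower_twin_above_cutoff",
                          "lower_score": lower, "abs_diff_t": diff})
            n_conc += 1
        elif diff < k * config.discordance_sd:
            audit.append({"pair_id": pair.pair_id,
                          "rule": "difference_below_sd",
                          "lower_score": lower, "abs_diff_t": diff})
            n_conc += 1
        else:
            n_disc += 1
    return ConcordanceResult(n_concordant=n_conc, n_discordant=n_disc,
                             audit=audit)


def reported_concordance(cohort: Cohort) -> ConcordanceResult:
    """Concordance by reported diagnosis flags alone (no correction)."""
    flagged = [p for p in cohort if p.dx_t1 is not None and p.dx_t2 is not None]
    if not flagged:
        raise ValueError("no reported-diagnosis flags in cohort")
    d = sum(1 for p in flagged if p.dx_t1 != p.dx_t2)
    return concordance_from_counts(len(flagged) - d, d)


@dataclass
class StraddleResult:
    """Pairs whose lower twin sits in the subthreshold band while the
    co-twin is clinically affected, in ascending order of the lower score."""

    count: int
    n_pairs: int
    fraction: float
    ordered_pairs: list[dict]


def straddle_analysis(cohort: Cohort, config: AnalysisConfig | None = None
                      ) -> StraddleResult:
    """Count pairs straddling the clinical threshold from the subthreshold
    band [floor, threshold), and emit the display ordering (ascending by
    the lower-scoring twin's T). Both boundary rules are inclusive at the
    floor and at the threshold for the co-twin."""
    config = config or AnalysisConfig()
    cohort.require_nonempty()
    rows = []
    count = 0
    for pair in cohort:
        lower = min(pair.score_t1, pair.score_t2)
        upper = max(pair.score_t1, pair.score_t2)
        straddling = (config.subthreshold_floor <= lower < config.clinical_threshold
                      and upper >= config.clinical_threshold)
        count += straddling
        rows.append({"pair_id": pair.pair_id, "lower": lower, "upper": upper,
                     "straddling_band": bool(straddling)})
    rows.sort(key=lambda r: (r["lower"], r["pair_id"]))
    return StraddleResult(count=count, n_pairs=len(cohort),
                          fraction=count / len(cohort), ordered_pairs=rows)
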