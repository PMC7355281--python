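# twinconcord

Quantitative analysis of concordance and discordance in monozygotic (MZ)
twins measured on a continuous trait scale — built around autistic trait
severity on the Social Responsiveness Scale (SRS-2), for behavior-genetics
and psychiatric-epidemiology researchers working with twin registry data.

## The problem

Classical twin concordance is categorical: a pair is "discordant" when one
twin carries a diagnosis and the other does not, regardless of how close
their trait scores are. For a continuously distributed trait this misreads
two situations:

* pairs **straddling** the clinical threshold (lower twin in the
  subthreshold band, 50–65T; co-twin just above 65T) are categorically
  discordant yet quantitatively similar, and
* parent-reported discordance often dissolves when both twins are measured —
  either the "unaffected" twin scores above the clinical cutoff, or the
  twins differ by less than one clinical-population standard deviation.

Conversely, restricting analysis to clinically affected pairs (both twins
≥ 65T) attenuates the twin correlation by restriction of range, so a weak
observed correlation among affected pairs is only informative relative to
the correlation *expected* under truncation alone.

## What the package computes

* **Concordance statistics** — pairwise `C/(C+D)` and probandwise
  `2C/(2C+D)` rates from counts or from classified cohorts.
* **Quantitative discordance classifier** — a pair is discordant iff
  `|t₁ − t₂| ≥ k·σ_c` (default `k = 1.5`, `σ_c = 18.1` T-points, the
  clinical-population SD) **and** the twins fall on opposite sides of the
  clinical threshold (65T, boundary counted as affected).
* **Reported-discordance correction** — reclassifies reported-discordant
  pairs whose lower twin exceeds the cutoff or whose difference is below
  `k·σ_c` (default `k = 1`), with a per-pair audit trail.
* **Severity statistics** — twin-difference distributions, Pearson /
  Spearman / double-entry-ICC twin correlations, familiality variance
  (`100·r²`), severity-vs-difference and age-vs-difference associations,
  and the threshold-straddle analysis.
* **Synthetic twin cohorts** — a calibrated generator
  (`t₁ = μ + d/2, t₂ = μ − d/2` with Gaussian pair-level severity `μ` and
  within-pair difference `d`, optionally variance-amplified above the
  clinical threshold), with presets matching the published epidemiologic
  (288 pairs, mean 49T, twin *r* ≈ .75) and clinical (78 pairs, mean 78T,
  twin *r* ≈ .27) cohort statistics, plus SCI/RRB subscales and ADOS
  scores.
* **Truncation simulation** — Gaussian-copula resampling from a score pool
  with the realized pair correlation bisection-calibrated to a target
  (0.77), truncated at the clinical cutoff, against an analytic
  truncated-bivariate-normal oracle computed by numerical integration.

## Worked example

```python
from twinconcord import (AnalysisConfig, make_reclassification_fixture,
                         reported_concordance, correct_reported_concordance,
                         params_from_preset, generate_cohort,
                         difference_summary, twin_correlation,
                         ScorePool, expected_vs_observed, round_half_up)

cfg = AnalysisConfig()

# correction of parent-reported discordance (deterministic 23-pair fixture)
fix = make_reclassification_fixture(cfg)
rep = reported_concordance(fix)
cor = correct_reported_concordance(fix, cfg, k=1.0)
print(rep.n_discordant, round_half_up(rep.rate_pairwise))   # 9 0.61
print(cor.n_discordant, round_half_up(cor.rate_pairwise))   # 2 0.91

# synthetic epidemiologic cohort at the published size
coh = generate_cohort(params_from_preset("epidemiologic", cfg), "epidemiologic", cfg)
s = difference_summary(coh, "raw", cfg)
r = twin_correlation(coh, "SRS_total", "pearson", cfg)
print(f"{s.mean_absdiff:.2f} {r.r:.3f} {r.r2_percent}%")    # 7.84 0.776 60%

# expected correlation among affected pairs under truncation alone
pool = ScorePool.synthetic_population(seed=cfg.seed)
res = expected_vs_observed(pool, 0.77, 65.0, None, cfg, n=10_000, seed=cfg.seed)
print(f"{res.r_full:.3f} {res.n_survivors} {res.r_truncated:.3f}")  # 0.758 440 0.462
```

The fixture's nine reported-discordant pairs shrink to two after the
quantitative correction, raising the concordance rate from 0.61 to 0.91.
The synthetic epidemiologic cohort reproduces the narrow difference
distribution (mean ≈ 7.7 raw points) and strong twin correlation
(*r* ≈ .75, familiality ≈ 57% of variance) it was calibrated to, within
sampling error at n = 288. In the truncation run, pairs constrained to
*r* = 0.77 retain a correlation of ≈ 0.4–0.5 among the ~4% of pairs
surviving a 65T double truncation — so an observed correlation near zero
among affected pairs indicates attenuation beyond restriction of range.

A CLI mirrors the library (`twinconcord simulate | classify | correct |
stats | truncsim | run`); `twinconcord run --out report.json` executes the
whole pipeline on synthetic presets and writes a machine-readable report.

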