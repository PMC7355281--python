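# Methods

## Data model and score scales

The unit of analysis is the MZ twin pair, stored wide (one row per pair)
because every statistic is pair-centric. SRS-2 total scores exist on two
scales: the raw sum (0–195) and the norm-referenced T-score (population
mean 50, SD 10). The published norm tables are sex-specific and not
reproduced here; instead a single affine map

    T = 0.55 · raw + 25

links the scales. The slope/intercept defaults were chosen for joint
consistency of the summary statistics the analysis is calibrated to: an
epidemiologic cohort with T-SD 7.6 and mean raw twin difference 7.7, and a
clinical cohort with T-SD 18.5, twin correlation 0.27 and mean raw
difference 33.0 are mutually consistent only for a slope near 0.55 (the
calibration identity below then implies an individual-score T-SD of 18.8,
within 5% of 18.5). Both parameters are configurable; because the map is
affine, every Pearson correlation downstream is identical on either scale.
When raw and T are both recorded they must agree with the map within 1
T-point (rounding slack of score tables); validation is total — every
input row is either accepted or rejected with a row-numbered diagnostic.

T-scores are accepted in [30, 130] (the widest observed clinical range,
35–128T, plus margin), ages in [0, 30] years.

## Concordance and the quantitative discordance criterion

Counts of concordant (C) and discordant (D) pairs yield the pairwise rate
C/(C+D) and the probandwise rate 2C/(2C+D); the probandwise form counts
each concordant pair twice and never falls below the pairwise form
(difference CD/((2C+D)(C+D)) ≥ 0). Published twin-registry rates labelled
"probandwise" in this literature often equal the pairwise ratio of the
printed counts (50/55 = 0.91, 14/23 = 0.61, 64/78 = 0.82), so reproduction
targets use the pairwise formula while both are always reported. Printed
2-decimal comparisons use half-up rounding.

A pair is quantitatively discordant iff both:

1. magnitude — |t₁ − t₂| ≥ k · σ_c, with σ_c = 18.1 T-points (the
   clinical-population SD) and k = 1.5 for classification; boundary
   inclusive (a difference exactly at k·σ_c meets the criterion);
2. threshold — the twins fall on opposite sides of the 65T clinical
   cutoff, a twin exactly at 65T counting as affected (min < 65 ≤ max).

σ_c is applied on the T scale. Pairs that satisfy (2) but not (1) are
labelled `straddling_subcriterion`; the remaining pairs are concordant
affected/unaffected. The four labels partition every valid cohort and are
invariant to twin order.

The reported-discordance correction takes parent-reported diagnosis flags
as given and reclassifies a reported-discordant pair as concordant when
(a) the lower-scoring twin is at or above the cutoff, or (b) the
difference is under k·σ_c with k = 1.0 (one full clinical SD — the
correction deliberately uses a weaker magnitude requirement than the
classifier, since it only needs evidence that the pair is *not* clearly
discordant). Reported-concordant pairs are never touched, so the
correction can only decrease D and never changes C + D.

The straddle analysis counts pairs whose lower twin lies in
[50T, 65T) — floor inclusive — with the co-twin ≥ 65T, and orders pairs by
the lower twin's score for display. The exact fraction is reported
(13/78 = 16.7%) rather than any pre-rounded value.

## Synthetic cohort generator

Scores are generated on the raw scale as

    raw₁ = μ + d/2,   raw₂ = μ − d/2,
    μ ~ N(m, σ_μ²),   d ~ N(0, σ_d²),  μ ⊥ d,

so σ_μ² is the familial (pair-level) variance and σ_d² the non-shared
variance. Closed forms E|d| = σ_d·√(2/π) and
r = (σ_μ² − σ_d²/4)/(σ_μ² + σ_d²/4) invert the model exactly:

    σ_d = E|d|·√(π/2),   σ_μ² = (σ_d²/4)·(1+r)/(1−r).

Presets encode the study conditions: epidemiologic (288 pairs, mean 49T,
r = .754, E|d| = 7.7 raw), IAN (23), AGRE (55) and the combined clinical
group (78 pairs, mean 78T, r = .27, E|d| = 33.0 raw). Sex ratios and age
ranges are metadata only — the analysis this emulates found no sex or age
effects, so the generator draws them independently of scores.

Severity-dependent discordance variance is modelled as a hard regime
switch: pairs whose latent mean severity (on the T scale) is at or above
the clinical threshold draw d with σ₁ = amplification · σ₀. The switch is
keyed on the latent μ, not observed scores, to keep classification tests
non-circular. Default amplification is 1.0 (calibration-faithful: the
closed-form targets are met exactly in expectation); 3.0 is used where an
amplified regime is the point of the experiment (the expected-vs-observed
gap, regime monotonicity). No functional form for the transition is
published, so the step is the simplest faithful choice.

Known limitation: with this hard-step regime the severity-vs-|d| Spearman
association is positive only in proportion to the above-threshold mass.
At the 65T threshold the epidemiologic preset has ≈ 1% of pairs above, so
its association is positive but small (≈ +0.02 at n = 288, versus +0.33
reported for real epidemiologic twins, where difference variance plausibly
grows continuously with severity); the clinical preset with amplification
has ≈ 77% above and shows a *positive* association (≈ +0.24), not the
near-zero reported for real clinical twins. The Monte-Carlo sign tests
therefore exercise the regime with the threshold placed inside the score
range (where the effect is identified) and the near-zero property with the
regime off. Passing tests show the generator realises its own model, not
that the model captures every feature of registry data.

Subscale scores (SCI, RRB) put half of their pair-level variance on the
total-score latent μ and half on a subscale-specific pair factor, with the
twin-specific residual set so the squared twin correlation equals the
preset variance share (epidemiologic 57%/48%, clinical 6%/20%). ADOS
social-affect scores are an affine function of each twin's latent severity
plus independent clinician-instrument noise with reliability
ados_r / r (so the ADOS twin correlation hits ados_r = 0.21 before
rounding), mapped to a 0–20 integer scale centred at 10 with ≈ 4 points
per severity SD — the scale bounds are not published and are configurable.
(Note that an ADOS twin correlation of 0.21 corresponds to a familiality
share of 100·0.21² ≈ 4.4%, which rounds to 4%, not the 5% sometimes
quoted alongside it; `familiality_variance` always reports the exact r².)

Out-of-range scores are clamped (on the raw scale, to the intersection of
the raw and T validity ranges, so the affine relation stays exact) and
logged rather than re-drawn; re-drawing would distort the calibrated
moments less transparently. Clamping touches ≈ 0.5–1% of scores at the
default presets and biases mean |d| slightly downward (≈ 1% at the
clinical preset), well inside the 3-SE recovery bands used in tests.
Identical (params, seed) gives bit-identical cohorts via
`numpy.random.default_rng`.

The 23-pair reclassification fixture is hard-coded (seed-independent):
14 reported-concordant pairs, 3 reported-discordant with the lower twin
above 65T, 4 with differences under 18.1T, and 2 meeting both discordance
conditions, so the k = 1 correction yields 21/23 = 0.91 (2 dp).

## Truncation simulation

The resampling simulation draws pairs from a score pool under a Gaussian
copula: latent (z₁, z₂) bivariate normal with correlation ρ, each margin
mapped through the pool's empirical quantile function (`inverted_cdf`,
i.e. with-replacement sampling — only pool values are emitted, and the
pool's marginal distribution is preserved exactly). ρ is calibrated by
bisection so the realized Pearson correlation hits the target within
± 0.01 on a dedicated 10⁵-pair calibration draw held fixed across
bisection steps (common random numbers make the realized correlation a
deterministic, monotone function of ρ); the reported pairs come from a
separate stream so calibration noise does not leak into results. How the
original analysis induced its correlation constraint is not published;
the copula is adopted as the canonical interpretation because it is the
unique construction that both preserves with-replacement marginals and
admits a single correlation knob.

Truncation keeps pairs with both members ≥ threshold (boundary
inclusive). The default synthetic population pool is a skew-normal
(shape 4) location/scale-adjusted to mean 50T, SD 10T — right-skewed as
quantitative autistic-trait distributions are. The published expected
truncated correlation (0.15) was computed from an undeposited 6,000-score
registry pool, so it is not desk-reproducible; with the synthetic pool the
expected correlation at a 65T double truncation is ≈ 0.35–0.46 depending
on draw (≈ 4% survivors). The package instead verifies the three
properties the contrast rests on: oracle equivalence, attenuation
ordering, and the expected ≫ observed gap against amplified-discordance
clinical cohorts.

The analytic oracle `bvn_truncated_corr(ρ, h, mode)` computes the
correlation of a standard bivariate normal restricted to {X ≥ h, Y ≥ h}
(or {X ≥ h}) by writing Y = ρX + √(1−ρ²)Z, which reduces all first and
second moments to 1-D integrals whose inner Z-moments are closed-form
normal tail expressions; `scipy.integrate.quad` over [h, max(h,0)+9]
(beyond which the Gaussian mass is < 1e-17) gives absolute accuracy well
below the 1e-4 tolerance, including near-degenerate ρ = 0.999. Test
expectations for the oracle were frozen from an independent
rejection-sampling Monte Carlo (10⁷ draws per cell). A published
table-based range (0.50–0.62, quoted for thresholds spanning the upper
70% to the upper 30% at ρ = 0.75) cannot describe double truncation,
whose attenuation is monotone the other way (this oracle: 0.59 keeping
the upper 70%, 0.46 keeping the upper 30%); single truncation of one
margin does span those magnitudes (0.62 and 0.50 respectively), though
with attenuation *increasing* toward the stricter cutoff. The package
computes both modes and documents the ambiguity rather than forcing
agreement with either reading.

## Pipeline, sizes and determinism

`run_pipeline` executes difference summaries → correlations/familiality →
severity and age associations → concordance (quantitative, reported,
corrected) → straddle analysis → truncation simulation, writing a
stable-key JSON report; a stage failure aborts with the stage name and the
completed stages flagged. All randomness flows from
`AnalysisConfig.seed` (default 20191218), so a rerun with the same config
is byte-identical.

Problem sizes: report-scale runs use the published cohort sizes
(288/23/55/78); calibration-recovery checks use 10⁴ pairs (3-SE bands);
copula calibration uses 10⁵ latent draws; oracle-equivalence simulations
10⁵–2·10⁵ pairs; replicate-based properties use 100–200 cohorts. p-values
are auxiliary large-sample outputs with no multiple-testing correction
(none is performed in this design).
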