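"""Concordance rates, the quantitative discordance classifier, the
reported-discordance correction, and the straddle analysis."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from twinconcord import (AnalysisConfig, Cohort, TwinPair, classify_pair,
                         concordance_from_counts,
                         correct_reported_concordance, quantitative_concordance,
                         reported_concordance, round_half_up, straddle_analysis)
from twinconcord.concordance import LABELS

from conftest import pair


class TestConcordanceFromCounts:
    @pytest.mark.parametrize("c, d, expected", [
        (50, 5, 0.91),    # AGRE
        (14, 9, 0.61),    # IAN as reported
        (64, 14, 0.82),   # combined clinical
    ])
    def test_pairwise_rate_matches_published_2dp(self, c, d, expected):
        res = concordance_from_counts(c, d)
        assert round_half_up(res.rate_pairwise) == expected

    def test_probandwise_formula(self):
        res = concordance_from_counts(50, 5)
        assert res.rate_probandwise == pytest.approx(100 / 105)

    def test_all_concordant_gives_unity(self):
        res = concordance_from_counts(7, 0)
        assert res.rate_pairwise == res.rate_probandwise == 1.0

    def test_no_pairs_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            concordance_from_counts(0, 0)

    @given(c=st.integers(0, 500), d=st.integers(0, 500))
    @settings(derandomize=True, deadline=None)
    def test_probandwise_dominates_pairwise(self, c, d):
        """2C/(2C+D) - C/(C+D) = CD/((2C+D)(C+D)) >= 0, equality iff C or D
        is zero."""
        if c + d == 0:
            return
        res = concordance_from_counts(c, d)
        assert res.rate_probandwise >= res.rate_pairwise
        if c > 0 and d > 0:
            assert res.rate_probandwise > res.rate_pairwise
        else:
            assert res.rate_probandwise == res.rate_pairwise


class TestClassifier:
    def test_discordant_pair(self, config):
        c = classify_pair(pair(90.0, 50.0), config)
        assert c.label == "discordant"
        assert c.meets_magnitude and c.straddles_threshold
        assert c.abs_diff_t == 40.0

    def test_both_above_is_concordant_affected_for_any_k(self, config):
        for k in (0.1, 1.5, 10.0):
            c = classify_pair(pair(80.0, 70.0), config.with_(
                discordance_multiplier=k))
            assert c.label == "concordant_affected"

    def test_straddling_subcriterion(self, config):
        c = classify_pair(pair(64.0, 66.0), config)
        assert c.label == "straddling_subcriterion"
        assert c.straddles_threshold and not c.meets_magnitude

    def test_at_threshold_counts_as_affected(self, config):
        assert classify_pair(pair(65.0, 66.0), config).label == \
            "concordant_affected"
        assert classify_pair(pair(64.9, 65.0), config).label == \
            "straddling_subcriterion"

    def test_magnitude_boundary_is_inclusive(self, config):
        # |d| exactly k * sd meets the criterion: 1.5 * 18.1 = 27.15
        c = classify_pair(pair(60.0, 60.0 + 1.5 * 18.1), config)
        assert c.meets_magnitude and c.label == "discordant"

    @given(t1=st.floats(30, 130), t2=st.floats(30, 130))
    @settings(derandomize=True, deadline=None)
    def test_swap_symmetry_and_partition(self, t1, t2):
        config = AnalysisConfig()
        a = classify_pair(pair(t1, t2), config)
        b = classify_pair(pair(t2, t1), config)
        assert a.label == b.label
        assert a.label in LABELS
        # exhaustive and exclusive: exactly one label, consistent with flags
        assert (a.label == "discordant") == (
            a.meets_magnitude and a.straddles_threshold)

    @given(t1=st.floats(30, 130), t2=st.floats(30, 130))
    @settings(derandomize=True, deadline=None)
    def test_discordance_monotone_in_k(self, t1, t2):
        config = AnalysisConfig()
        labels = [classify_pair(pair(t1, t2), config.with_(
            discordance_multiplier=k)).label for k in (0.5, 1.0, 1.5, 3.0)]
        # once a pair stops being discordant as k grows it never resumes
        disc = [lab == "discordant" for lab in labels]
        assert disc == sorted(disc, reverse=True)

    def test_missing_score_rejected(self, config):
        with pytest.raises(ValueError, match="required"):
            classify_pair(TwinPair(pair_id="x", score_t1=70.0,
                                   score_t2=float("nan")), config)


class TestCorrection:
    def test_fixture_corrected_rate_is_091(self, fixture_cohort, config):
        res = correct_reported_concordance(fixture_cohort, config, k=1.0)
        assert res.n_discordant == 2
        assert res.n_concordant == 21
        assert round_half_up(res.rate_pairwise) == 0.91

    def test_fixture_reported_rate_is_061(self, fixture_cohort):
        res = reported_concordance(fixture_cohort)
        assert (res.n_concordant, res.n_discordant) == (14, 9)
        assert round_half_up(res.rate_pairwise) == 0.61

    def test_audit_records_rules(self, fixture_cohort, config):
        res = correct_reported_concordance(fixture_cohort, config, k=1.0)
        rules = [e["rule"] for e in res.audit]
        assert rules.count("lower_twin_above_cutoff") == 3
        assert rules.count("difference_below_sd") == 4

    def test_no_reported_discordance_leaves_counts_unchanged(self, config):
        cohort = Cohort(label="c", pairs=[
            pair(70.0, 75.0, "a", dx_t1=True, dx_t2=True),
            pair(80.0, 90.0, "b", dx_t1=True, dx_t2=True),
        ])
        res = correct_reported_concordance(cohort, config)
        assert (res.n_concordant, res.n_discordant) == (2, 0)
        assert res.audit == []

    def test_no_rule_firing_leaves_discordant(self, config):
        cohort = Cohort(label="c", pairs=[
            pair(40.0, 90.0, f"p{i}", dx_t1=True, dx_t2=False)
            for i in range(9)
        ])
        res = correct_reported_concordance(cohort, config, k=1.0)
        assert res.n_discordant == 9

    def test_correction_never_increases_discordance(self, fixture_cohort, config):
        before = reported_concordance(fixture_cohort)
        for k in (0.25, 0.5, 1.0, 1.5, 2.0):
            after = correct_reported_concordance(fixture_cohort, config, k=k)
            assert after.n_discordant <= before.n_discordant
            assert after.n_pairs == before.n_pairs

    def test_missing_dx_flags_instructive_error(self, toy_cohort, config):
        with pytest.raises(ValueError, match="classify_pair"):
            correct_reported_concordance(toy_cohort, config)


class TestQuantitativeConcordance:
    def test_partition_of_cohort(self, fixture_cohort, config):
        from twinconcord import classify_cohort
        classes = classify_cohort(fixture_cohort, config)
        assert len(classes) == len(fixture_cohort)
        res = quantitative_concordance(fixture_cohort, config)
        assert res.n_pairs == len(fixture_cohort)

    def test_discordance_count_monotone_in_k(self, fixture_cohort, config):
        counts = [quantitative_concordance(
            fixture_cohort, config.with_(discordance_multiplier=k)).n_discordant
            for k in (0.25, 0.5, 1.0, 1.5, 3.0)]
        assert counts == sorted(counts, reverse=True)


class TestStraddle:
    def test_counts_subthreshold_band_pairs(self, fixture_cohort, config):
        res = straddle_analysis(fixture_cohort, config)
        # fixture rule-b pairs (55/52/60/58 vs >=65T co-twin) straddle from
        # the band; the 2 truly discordant pairs have lower twins below 50T
        assert res.count == 4
        assert res.fraction == pytest.approx(4 / 23)

    def test_floor_boundary_inclusive(self, config):
        cohort = Cohort(label="c", pairs=[pair(50.0, 66.0, "a"),
                                          pair(49.9, 66.0, "b"),
                                          pair(70.0, 80.0, "c")])
        res = straddle_analysis(cohort, config)
        assert res.count == 1
        flags = {r["pair_id"]: r["straddling_band"] for r in res.ordered_pairs}
        assert flags == {"a": True, "b": False, "c": False}

    def test_all_above_threshold_counts_zero(self, config):
        cohort = Cohort(label="c", pairs=[pair(70.0, 80.0, "a"),
                                          pair(66.0, 90.0, "b")])
        assert straddle_analysis(cohort, config).count == 0

    def test_display_order_ascending_by_lower_twin(self, fixture_cohort, config):
        res = straddle_analysis(fixture_cohort, config)
        lowers = [r["lower"] for r in res.ordered_pairs]
        assert lowers == sorted(lowers)

    def test_empty_cohort_rejected(self, config):
        with pytest.raises(ValueError, match="empty"):
            straddle_analysis(Cohort(label="e", pairs=[]), config)


def test_straddle_study_scale_proportion(config):
    """A 78-pair clinical cohort built so 13 pairs straddle the band gives
    the published count and the exact fraction 13/78."""
    pairs = []
    for i in range(13):
        pairs.append(pair(52.0 + i, 70.0 + i, f"s{i}"))
    for i in range(65):
        pairs.append(pair(66.0 + (i % 30), 75.0 + (i % 40), f"c{i}"))
    res = straddle_analysis(Cohort(label="clin", pairs=pairs), config)
    assert res.count == 13
    assert res.fraction == pytest.approx(13 / 78)
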