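"""Random-effects pooling, leave-one-out refits and replication-selection rules."""

import math

import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from repliclin import (
    CandidateDescriptor,
    EffectMeasure,
    EvidenceTier,
    MetaAnalysisSet,
    MetaStudyRecord,
    StudyDescriptor,
    check_meta_eligibility,
    contribution_fraction,
    leave_one_out,
    pool_random_effects,
    preceding_mass_exceeds,
    select_replication,
)
from repliclin.meta_reanalysis import mh_common_log_effect, read_studies_csv


def iv_study(study_id, log_effect, se, *, is_index=False, year=None, n=None):
    return MetaStudyRecord(
        study_id=study_id,
        publication_year=year,
        n=n,
        log_effect=log_effect,
        se=se,
        is_index=is_index,
    )


def dl_oracle(y, se):
    """Plain-formula DerSimonian-Laird pooling, written out independently."""
    y, se = np.asarray(y), np.asarray(se)
    w = 1 / se**2
    mu_f = (w * y).sum() / w.sum()
    q = (w * (y - mu_f) ** 2).sum()
    tau2 = max(0.0, (q - (len(y) - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    w_star = 1 / (se**2 + tau2)
    return (w_star * y).sum() / w_star.sum(), tau2


class TestPooling:
    def test_two_identical_studies_pool_to_themselves(self):
        studies = [iv_study("a", -0.3, 0.1), iv_study("b", -0.3, 0.1)]
        result = pool_random_effects(MetaAnalysisSet(tuple(studies), EffectMeasure.HR))
        assert result.estimate.point == pytest.approx(math.exp(-0.3))
        assert result.tau2 == 0.0 and result.q == pytest.approx(0.0)

    def test_heterogeneous_studies_match_dl_oracle(self):
        y, se = [-0.5, 0.0, 0.3], [0.2, 0.15, 0.25]
        studies = [iv_study(f"s{i}", yi, si) for i, (yi, si) in enumerate(zip(y, se))]
        result = pool_random_effects(MetaAnalysisSet(tuple(studies), EffectMeasure.RR))
        mu_oracle, tau2_oracle = dl_oracle(y, se)
        assert math.log(result.estimate.point) == pytest.approx(mu_oracle)
        assert result.tau2 == pytest.approx(tau2_oracle)

    def test_matches_statsmodels_dl(self):
        y, se = [-0.5, 0.0, 0.3], [0.2, 0.15, 0.25]
        studies = [iv_study(f"s{i}", yi, si) for i, (yi, si) in enumerate(zip(y, se))]
        result = pool_random_effects(MetaAnalysisSet(tuple(studies), EffectMeasure.RR))
        sm = combine_effects(np.array(y), np.array(se) ** 2, method_re="dl")
        sm_frame = sm.summary_frame()
        assert math.log(result.estimate.point) == pytest.approx(
            sm_frame.loc["random effect", "eff"]
        )
        assert result.tau2 == pytest.approx(sm.tau2)

    def test_mh_common_risk_ratio_matches_hand_weights(self):
        sets = [(10, 100, 20, 100), (15, 100, 15, 100)]
        # Textbook MH: sum(a*n2/N) / sum(c*n1/N) = 12.5 / 17.5.
        assert math.exp(mh_common_log_effect(sets, EffectMeasure.RR)) == pytest.approx(
            12.5 / 17.5
        )

    def test_mh_common_odds_ratio_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        sets = [(10, 100, 20, 100), (15, 100, 15, 100)]
        tables = [
            np.array([[a, t1 - a], [c, t2 - c]]) for a, t1, c, t2 in sets
        ]
        st_or = StratifiedTable(tables).oddsratio_pooled
        assert math.exp(mh_common_log_effect(sets, EffectMeasure.OR)) == pytest.approx(st_or)

    def test_count_studies_with_no_heterogeneity_use_mh_estimate(self):
        counts = [(12, 120, 24, 120), (12, 120, 24, 120)]
        studies = tuple(
            MetaStudyRecord(study_id=f"c{i}", arm_counts=c) for i, c in enumerate(counts)
        )
        result = pool_random_effects(MetaAnalysisSet(studies, EffectMeasure.RR))
        assert result.method == "MH+DL"
        assert result.estimate.point == pytest.approx(0.5)

    def test_single_study_returned_verbatim(self):
        result = pool_random_effects(
            MetaAnalysisSet((iv_study("solo", 0.2, 0.1),), EffectMeasure.RR)
        )
        assert result.single_study and result.method == "single-study"
        assert result.estimate.point == pytest.approx(math.exp(0.2))

    def test_pooled_effect_inside_convex_hull(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.normal(0, 0.5, size=4)
            se = rng.uniform(0.05, 0.4, size=4)
            studies = [iv_study(f"s{i}", yi, si) for i, (yi, si) in enumerate(zip(y, se))]
            result = pool_random_effects(MetaAnalysisSet(tuple(studies), EffectMeasure.RR))
            assert y.min() - 1e-12 <= math.log(result.estimate.point) <= y.max() + 1e-12

    def test_equal_se_zero_tau2_is_arithmetic_mean(self):
        y = [-0.2, -0.25, -0.3]  # low spread -> Q < k-1 -> tau2 = 0
        studies = [iv_study(f"s{i}", yi, 0.3) for i, yi in enumerate(y)]
        result = pool_random_effects(MetaAnalysisSet(tuple(studies), EffectMeasure.RR))
        assert result.tau2 == 0.0
        assert math.log(result.estimate.point) == pytest.approx(np.mean(y))

    def test_removing_a_study_at_the_pooled_value_is_a_fixed_point(self):
        y = [-0.2, -0.3]
        studies = [iv_study("a", y[0], 0.2), iv_study("b", y[1], 0.2)]
        pooled = math.log(
            pool_random_effects(MetaAnalysisSet(tuple(studies), EffectMeasure.RR)).estimate.point
        )
        extended = studies + [iv_study("c", pooled, 0.25, is_index=True)]
        with_extra = pool_random_effects(MetaAnalysisSet(tuple(extended), EffectMeasure.RR))
        assert with_extra.tau2 == 0.0
        assert math.log(with_extra.estimate.point) == pytest.approx(pooled)
        after_removal = leave_one_out(MetaAnalysisSet(tuple(extended), EffectMeasure.RR))
        assert math.log(after_removal.estimate.point) == pytest.approx(pooled)


class TestLeaveOneOut:
    def test_two_study_set_returns_other_study_exactly(self):
        other = iv_study("other", -0.42, 0.17)
        index = iv_study("index", -0.9, 0.3, is_index=True)
        result = leave_one_out(MetaAnalysisSet((index, other), EffectMeasure.HR))
        assert result.single_study
        assert math.log(result.estimate.point) == pytest.approx(-0.42)

    def test_identical_studies_unchanged_by_removal(self):
        studies = tuple(
            iv_study(f"s{i}", -0.3, 0.1, is_index=(i == 0)) for i in range(4)
        )
        full = pool_random_effects(MetaAnalysisSet(studies, EffectMeasure.RR))
        reduced = leave_one_out(MetaAnalysisSet(studies, EffectMeasure.RR))
        assert reduced.estimate.point == pytest.approx(full.estimate.point)

    def test_three_study_set_matches_oracle_on_remaining_two(self):
        index = iv_study("index", -0.8, 0.2, is_index=True)
        rest = [iv_study("a", -0.2, 0.15), iv_study("b", 0.1, 0.25)]
        result = leave_one_out(MetaAnalysisSet((index, *rest), EffectMeasure.RR))
        mu_oracle, _ = dl_oracle([-0.2, 0.1], [0.15, 0.25])
        assert math.log(result.estimate.point) == pytest.approx(mu_oracle)

    def test_missing_index_or_empty_remainder_rejected(self):
        no_index = MetaAnalysisSet((iv_study("a", 0.1, 0.2),), EffectMeasure.RR)
        with pytest.raises(ValueError, match="no index"):
            leave_one_out(no_index)
        only_index = MetaAnalysisSet(
            (iv_study("a", 0.1, 0.2, is_index=True),), EffectMeasure.RR
        )
        with pytest.raises(ValueError, match="nothing to pool"):
            leave_one_out(only_index)


class TestEligibilityRules:
    def _set(self, sizes_years, index_pos=0):
        studies = tuple(
            iv_study(f"s{i}", -0.2, 0.2, is_index=(i == index_pos), year=y, n=n)
            for i, (n, y) in enumerate(sizes_years)
        )
        return MetaAnalysisSet(studies, EffectMeasure.RR)

    def test_contribution_fraction(self):
        s = self._set([(100, 2010), (250, 2012), (150, 2014)])
        assert contribution_fraction(s) == pytest.approx(0.2)
        assert check_meta_eligibility(s)

    def test_index_only_contributes_everything(self):
        s = self._set([(100, 2010)])
        assert contribution_fraction(s) == 1.0
        assert not check_meta_eligibility(s)

    def test_preceding_mass(self):
        earlier = self._set([(100, 2015), (300, 2010), (200, 2012)])
        assert preceding_mass_exceeds(earlier)
        later = self._set([(100, 2010), (300, 2015), (200, 2012)])
        assert not preceding_mass_exceeds(later)
        tied = self._set([(100, 2012), (200, 2010), (200, 2015)])
        assert not preceding_mass_exceeds(tied)  # strict inequality


class TestSelectReplication:
    def test_higher_tier_always_eligible(self):
        original = StudyDescriptor(tier=EvidenceTier.UNCONTROLLED, n=50)
        rct = CandidateDescriptor("rct", EvidenceTier.RCT, n=30)
        assert select_replication(original, [rct]) is rct

    def test_same_tier_needs_equal_or_larger_n(self):
        original = StudyDescriptor(tier=EvidenceTier.RCT, n=400)
        same_size = CandidateDescriptor("same", EvidenceTier.RCT, n=400)
        smaller = CandidateDescriptor("small", EvidenceTier.RCT, n=399)
        assert select_replication(original, [same_size]) is same_size
        assert select_replication(original, [smaller]) is None

    def test_meta_analysis_needs_minor_index_contribution(self):
        original = StudyDescriptor(tier=EvidenceTier.RCT, n=400)
        heavy = CandidateDescriptor("meta", EvidenceTier.META_ANALYSIS, n=900, contribution=0.6)
        assert select_replication(original, [heavy]) is None
        light = CandidateDescriptor("meta", EvidenceTier.META_ANALYSIS, n=900, contribution=0.4)
        assert select_replication(original, [heavy, light]) is light

    def test_largest_n_wins_with_lexicographic_tie_break(self):
        original = StudyDescriptor(tier=EvidenceTier.RCT, n=100)
        a = CandidateDescriptor("alpha", EvidenceTier.RCT, n=500)
        b = CandidateDescriptor("beta", EvidenceTier.RCT, n=500)
        c = CandidateDescriptor("gamma", EvidenceTier.RCT, n=400)
        assert select_replication(original, [c, b, a]) is a


class TestStudiesCsv:
    def test_read_mixed_rows(self, tmp_path):
        path = tmp_path / "studies.csv"
        path.write_text(
            "study_id,year,n,events_a,total_a,events_b,total_b,log_effect,se,is_index\n"
            "big,2010,500,25,250,40,250,,,true\n"
            "small,2014,200,,,,,-0.35,0.21,false\n"
        )
        analysis = read_studies_csv(path, measure=EffectMeasure.RR)
        assert analysis.index_study.study_id == "big"
        assert analysis.studies[0].arm_counts == (25, 250, 40, 250)
        assert analysis.studies[1].log_effect == pytest.approx(-0.35)
        result = leave_one_out(analysis)
        assert math.log(result.estimate.point) == pytest.approx(-0.35)
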