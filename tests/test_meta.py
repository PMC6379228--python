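import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.meta_analysis import combine_effects

import genemeta as gm
from genemeta.contrasts import ContrastTable, GeneticModel
from genemeta.errors import InsufficientStudiesError, UndefinedEffectError
from genemeta.meta import (_iv_mean, contrast_tables, estimate_effect,
                           heterogeneity, pool, pool_fixed_mh, pool_random_dl,
                           select_method, sensitivity_loo, subgroup_analysis,
                           PoolingMethod)
from genemeta.study_data import Dataset


def table(a, b, c, d, model=GeneticModel.ALLELE, study_id="s"):
    return ContrastTable(a, b, c, d, model, study_id)


class TestEstimateEffect:
    def test_ciarmela_allele_matches_printed_single_study_row(self):
        e = estimate_effect(table(55, 45, 124, 160))
        assert e.or_value == pytest.approx(1.5771, abs=1e-4)
        assert (round(e.ci_low, 2), round(e.ci_high, 2)) == (1.00, 2.49)
        assert not e.corrected

    def test_balanced_table_is_null(self):
        e = estimate_effect(table(10, 10, 10, 10))
        assert e.log_or == pytest.approx(0.0)
        assert e.or_value == pytest.approx(1.0)
        assert e.ci_low < 1.0 < e.ci_high

    def test_zero_cell_gets_haldane_anscombe_correction(self):
        e = estimate_effect(table(0, 10, 5, 15))
        assert e.corrected
        assert e.or_value == pytest.approx((0.5 * 15.5) / (10.5 * 5.5))

    def test_empty_arm_raises(self):
        with pytest.raises(UndefinedEffectError):
            estimate_effect(table(0, 0, 5, 15))

    def test_ci_is_symmetric_on_log_scale(self):
        e = estimate_effect(table(30, 20, 25, 25))
        assert e.ci_low * e.ci_high == pytest.approx(e.or_value ** 2)


class TestFixedMH:
    def test_nine_study_allele_pool_matches_reported_total(self, fas670):
        res = pool_fixed_mh(contrast_tables(fas670, GeneticModel.ALLELE))
        assert res.k == 9
        assert round(res.or_value, 2) == 1.54
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.35, 1.77)
        assert res.p_value < 0.001
        assert sum(res.weights.values()) == pytest.approx(1.0)

    def test_single_table_reduces_to_study_or(self):
        t = table(55, 45, 124, 160)
        res = pool_fixed_mh([t])
        e = estimate_effect(t)
        assert res.or_value == pytest.approx(e.or_value)
        assert res.ci_low == pytest.approx(e.ci_low, rel=1e-12)
        assert res.ci_high == pytest.approx(e.ci_high, rel=1e-12)

    def test_duplicated_table_is_homogeneous(self):
        t = table(30, 20, 25, 25)
        res = pool_fixed_mh([t, table(30, 20, 25, 25, study_id="s2")])
        assert res.or_value == pytest.approx(estimate_effect(t).or_value)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientStudiesError):
            pool_fixed_mh([])

    def test_agrees_with_statsmodels_stratified_table(self, fas670):
        for model in GeneticModel:
            tabs = contrast_tables(fas670, model)
            mine = pool_fixed_mh(tabs)
            ref = StratifiedTable(
                [np.array([[t.a, t.b], [t.c, t.d]]) for t in tabs])
            assert mine.or_value == pytest.approx(ref.oddsratio_pooled,
                                                  rel=1e-12)
            lo, hi = ref.oddsratio_pooled_confint()
            assert mine.ci_low == pytest.approx(lo, rel=1e-9)
            assert mine.ci_high == pytest.approx(hi, rel=1e-9)

    def test_mh_close_to_inverse_variance_on_large_count_analyses(
            self, fixture_ds):
        worst = {"-670 A/G": 0.01, "-844 C/T": 0.01, "124 A/G": 0.025}
        for snp, bound in worst.items():
            recs = fixture_ds.for_snp(snp)
            for model in GeneticModel:
                tabs = contrast_tables(recs, model)
                mh = pool_fixed_mh(tabs).or_value
                mu, _ = _iv_mean([estimate_effect(t) for t in tabs])
                assert abs(mh - math.exp(mu)) / mh < bound

    def test_reciprocity_swapping_arms_inverts_pooled_or(self, fas670):
        tabs = contrast_tables(fas670, GeneticModel.ALLELE)
        res = pool_fixed_mh(tabs)
        inv = pool_fixed_mh([t.swap_arms() for t in tabs])
        assert inv.or_value == pytest.approx(1.0 / res.or_value, rel=1e-12)

    def test_pooled_or_within_per_study_range(self, fixture_ds):
        for snp in ("-670 A/G", "124 A/G", "-844 C/T"):
            for model in GeneticModel:
                tabs = contrast_tables(fixture_ds.for_snp(snp), model)
                ors = [estimate_effect(t).or_value for t in tabs]
                pooled = pool_fixed_mh(tabs).or_value
                assert min(ors) <= pooled <= max(ors)


class TestRandomDL:
    def test_nine_study_dominant_pool_matches_reported_total(self, fas670):
        ests = [estimate_effect(t)
                for t in contrast_tables(fas670, GeneticModel.DOMINANT)]
        res = pool_random_dl(ests, GeneticModel.DOMINANT)
        assert round(res.or_value, 2) == 1.90
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.35, 2.68)
        assert res.tau2 > 0

    def test_three_study_allele_pool_matches_reported_total(self, fixture_ds):
        ests = [estimate_effect(t) for t in contrast_tables(
            fixture_ds.for_snp("124 A/G"), GeneticModel.ALLELE)]
        res = pool_random_dl(ests)
        assert round(res.or_value, 2) == 0.99
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.47, 2.07)

    def test_homogeneous_studies_degenerate_to_fixed_iv(self):
        ests = [estimate_effect(table(30, 20, 25, 25, study_id=f"s{i}"))
                for i in range(3)]
        res = pool_random_dl(ests)
        mu, sw = _iv_mean(ests)
        assert res.tau2 == 0.0
        assert res.or_value == pytest.approx(math.exp(mu), rel=1e-12)

    def test_requires_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            pool_random_dl([estimate_effect(table(30, 20, 25, 25))])

    def test_agrees_with_statsmodels_combine_effects(self, fas670):
        for model in GeneticModel:
            ests = [estimate_effect(t) for t in contrast_tables(fas670, model)]
            mine = pool_random_dl(ests)
            ref = combine_effects(np.array([e.log_or for e in ests]),
                                  np.array([e.se ** 2 for e in ests]),
                                  method_re="dl")
            if ref.tau2 > 0:
                assert mine.tau2 == pytest.approx(ref.tau2, rel=1e-10)
                assert mine.or_value == pytest.approx(
                    math.exp(ref.mean_effect_re), rel=1e-10)
            else:
                # statsmodels leaves the moment estimate unclipped; the DL
                # definition truncates at zero (fixed-pooling degeneracy)
                mu, _ = _iv_mean(ests)
                assert mine.tau2 == 0.0
                assert mine.or_value == pytest.approx(math.exp(mu), rel=1e-12)


class TestHeterogeneity:
    def test_allele_model_p_het(self, fas670):
        ests = [estimate_effect(t)
                for t in contrast_tables(fas670, GeneticModel.ALLELE)]
        het = heterogeneity(ests)
        assert het.df == 8
        assert het.p_value == pytest.approx(0.0834, abs=5e-4)
        assert het.i2 == pytest.approx(42.6, abs=0.1)

    def test_identical_estimates_are_homogeneous(self):
        ests = [estimate_effect(table(30, 20, 25, 25, study_id=f"s{i}"))
                for i in range(4)]
        het = heterogeneity(ests)
        assert het.q_stat == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0
        assert het.p_value == pytest.approx(1.0)

    def test_two_study_q_matches_direct_summation(self, fixture_ds):
        tabs = contrast_tables(fixture_ds.for_snp("-844 C/T"),
                               GeneticModel.HETEROZYGOTE)
        ests = [estimate_effect(t) for t in tabs]
        # brute force: Q = sum w_i (theta_i - theta_bar)^2, w = 1/se^2
        th = np.array([e.log_or for e in ests])
        w = 1.0 / np.array([e.se for e in ests]) ** 2
        q_brute = float((w * (th - (w * th).sum() / w.sum()) ** 2).sum())
        assert heterogeneity(ests).q_stat == pytest.approx(q_brute, abs=1e-12)
        assert q_brute == pytest.approx(2.4511, abs=1e-4)

    def test_single_estimate_is_flagged_degenerate(self):
        het = heterogeneity([estimate_effect(table(30, 20, 25, 25))])
        assert het.degenerate
        assert (het.q_stat, het.df, het.p_value, het.i2) == (0.0, 0, 1.0, 0.0)


class TestSelectMethod:
    @pytest.mark.parametrize("i2, expected", [
        (42.6, PoolingMethod.FIXED_MH),   # allele model: fixed despite p_het<0.1
        (59.2, PoolingMethod.RANDOM_DL),  # -844 heterozygote: random
        (0.0, PoolingMethod.FIXED_MH),
        (50.0, PoolingMethod.RANDOM_DL),  # threshold is inclusive
    ])
    def test_i2_rule(self, i2, expected):
        assert select_method(10.0, 8, i2) is expected

    def test_threshold_is_configurable(self):
        assert select_method(10.0, 8, 40.0, threshold=30.0) \
            is PoolingMethod.RANDOM_DL


class TestSubgroups:
    def test_soc_subgroups_match_reported_rows(self, fixture_ds):
        res = subgroup_analysis(fixture_ds, "-670 A/G", GeneticModel.ALLELE,
                                by="soc")
        hb, pb = res["HB"], res["PB"]
        assert hb.k == 8 and round(hb.or_value, 2) == 1.54
        assert (round(hb.ci_low, 2), round(hb.ci_high, 2)) == (1.34, 1.77)
        assert pb.k == 1 and round(pb.or_value, 2) == 1.58  # single study

    def test_method_subgroups_match_reported_rows(self, fixture_ds):
        res = subgroup_analysis(fixture_ds, "-670 A/G", GeneticModel.ALLELE,
                                by="method")
        rflp = res["PCR-RFLP"]
        assert rflp.k == 6 and round(rflp.or_value, 2) == 1.50
        assert (round(rflp.ci_low, 2), round(rflp.ci_high, 2)) == (1.28, 1.76)
        assert res["PCR"].k == 3

    def test_unknown_key_raises(self, fixture_ds):
        with pytest.raises(KeyError):
            subgroup_analysis(fixture_ds, "-670 A/G", GeneticModel.ALLELE,
                              by="ethnicity")

    def test_single_group_equals_total(self, fixture_ds):
        # all -844 records are hospital-based
        res = subgroup_analysis(fixture_ds, "-844 C/T", GeneticModel.DOMINANT,
                                by="soc")
        total = pool(contrast_tables(fixture_ds.for_snp("-844 C/T"),
                                     GeneticModel.DOMINANT))
        assert list(res) == ["HB"]
        assert res["HB"] == total


class TestSensitivity:
    def test_leave_one_out_count_and_stability(self, fixture_ds):
        loo = sensitivity_loo(fixture_ds, "-670 A/G", GeneticModel.ALLELE)
        assert len(loo) == 9
        assert [sid for sid, _ in loo] == [r.study_id
                                           for r in fixture_ds.for_snp("-670 A/G")]
        for _, res in loo:
            assert res.k == 8
            assert res.or_value > 1 and res.ci_low > 1

    def test_two_studies_give_single_study_results(self, fixture_ds):
        loo = sensitivity_loo(fixture_ds, "-844 C/T", GeneticModel.ALLELE)
        assert [res.k for _, res in loo] == [1, 1]

    def test_omitting_an_added_duplicate_recovers_original(self, fixture_ds):
        recs = list(fixture_ds.for_snp("-670 A/G"))
        dup = gm.StudyRecord(**{**recs[0].__dict__, "study_id": "dup"})
        loo = sensitivity_loo(Dataset(recs + [dup]), "-670 A/G",
                              GeneticModel.ALLELE)
        original = pool(contrast_tables(recs, GeneticModel.ALLELE))
        recovered = dict(loo)["dup"]
        assert recovered.or_value == pytest.approx(original.or_value, rel=1e-12)
        assert recovered.method == original.method

    def test_requires_two_studies(self, fixture_ds):
        with pytest.raises(InsufficientStudiesError):
            sensitivity_loo(fixture_ds, "-1377 G/A", GeneticModel.ALLELE)
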