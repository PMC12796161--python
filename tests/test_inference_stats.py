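"""Permutation inference, corrected t-tests, FDR and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from modecca.data_io import standard_model_definitions
from modecca.experiments import planted_spec
from modecca.holdout_validation import ValidationConfig, run_multiple_holdout
from modecca.inference_stats import (
    block_permutation,
    compare_loadings_across_samples,
    corrected_resampled_ttest,
    fdr_adjust,
    fisher_z_mean,
    group_difference_stats,
    permutation_test,
    rank_biserial_from_u,
)
from modecca.synthetic_cohort import generate_cohort


class TestFisherZMean:
    def test_trivial_cases(self):
        assert fisher_z_mean([0.0, 0.0]) == 0.0
        assert fisher_z_mean([0.5, 0.5]) == pytest.approx(0.5)

    def test_closed_form_example(self):
        # atanh(0.8) = ln(3); mean z = ln(3)/2; tanh = (3-1)/(3+1) = 0.5
        assert fisher_z_mean([0.0, 0.8]) == pytest.approx(0.5)

    def test_rejects_degenerate_correlation(self):
        with pytest.raises(ValueError):
            fisher_z_mean([0.5, 1.0])

    @given(st.lists(st.floats(-0.99, 0.99), min_size=1, max_size=30))
    def test_lies_between_min_and_max(self, rs):
        z = fisher_z_mean(rs)
        assert min(rs) - 1e-12 <= z <= max(rs) + 1e-12


class TestBlockPermutation:
    def test_families_stay_intact(self, rng):
        blocks = np.repeat(["a", "b", "c", "d"], [2, 2, 3, 3])
        perm = block_permutation(blocks, rng)
        # each family's target positions must be a family of the same size
        for fam in "abcd":
            pos = np.flatnonzero(blocks == fam)
            sources = blocks[perm[pos]]
            assert len(set(sources)) == 1
            assert len(pos) == (blocks == sources[0]).sum()

    def test_free_mode_is_plain_permutation(self, rng):
        perm = block_permutation(np.arange(10), rng, mode="free")
        assert sorted(perm) == list(range(10))

    def test_is_a_permutation(self, rng):
        blocks = np.repeat(np.arange(20), 2)
        perm = block_permutation(blocks, rng)
        assert sorted(perm) == list(range(40))


@pytest.fixture(scope="module")
def null_summary():
    sizes = {"psqi": 3, "asr": 2, "gmv": 2, "motor": 3}
    spec = planted_spec(150, rho=0.0, seed=31, domain_sizes=sizes,
                        family_size_range=(1, 2))
    bundle = generate_cohort(spec)
    model = standard_model_definitions(bundle)["psqi"]
    config = ValidationConfig(n_outer=6, n_inner=3, grid=((0.5, 0.5),), seed=4)
    _, summary = run_multiple_holdout(bundle, model, config)
    return summary


@pytest.fixture(scope="module")
def planted_summary():
    sizes = {"psqi": 3, "asr": 2, "gmv": 2, "motor": 3}
    spec = planted_spec(300, rho=0.6, seed=17, domain_sizes=sizes,
                        family_size_range=(1, 2))
    bundle = generate_cohort(spec)
    model = standard_model_definitions(bundle)["psqi+asr+gmv"]
    config = ValidationConfig(n_outer=8, n_inner=3, grid=((0.3, 0.3), (0.9, 0.9)),
                              seed=6)
    _, summary = run_multiple_holdout(bundle, model, config)
    return summary


class TestPermutationTest:
    def test_planted_mode_detected(self, planted_summary):
        res = permutation_test(planted_summary, n_perm=199, seed=12)
        assert res.p_value <= 0.01

    def test_extreme_case_p_floor(self, planted_summary):
        # a strong observed statistic beats every null draw; the +1
        # convention keeps p strictly positive at 1/(n_perm + 1)
        res = permutation_test(planted_summary, n_perm=99, seed=13)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_null_p_not_small(self, null_summary):
        res = permutation_test(null_summary, n_perm=99, seed=14)
        assert res.p_value > 0.05

    def test_deterministic_given_seed(self, null_summary):
        a = permutation_test(null_summary, n_perm=29, seed=3)
        b = permutation_test(null_summary, n_perm=29, seed=3)
        np.testing.assert_array_equal(a.null, b.null)

    def test_monotone_statistic_invariance(self, null_summary):
        # p depends only on the ordering of null vs observed statistics,
        # so any monotone transform of the summary leaves it unchanged
        res = permutation_test(null_summary, n_perm=49, seed=8)
        obs_t, null_t = np.tanh(res.observed), np.tanh(res.null)
        p_t = (1 + np.sum(null_t >= obs_t)) / (1 + len(null_t))
        assert p_t == pytest.approx(res.p_value)

    def test_invalid_n_perm(self, null_summary):
        with pytest.raises(ValueError):
            permutation_test(null_summary, n_perm=0)


class TestCorrectedResampledTtest:
    def test_identical_scores(self):
        res = corrected_resampled_ttest([0.1, 0.2], [0.1, 0.2], 80, 20)
        assert res.t == 0.0 and res.p_value == 1.0

    def test_hand_computed_example(self):
        # d = [0.1, 0.2, 0.3]: var = 0.01, K = 3, n_test/n_train = 0.25
        # SE = sqrt((1/3 + 1/4) * 0.01) = 0.076376, t = 0.2/SE = 2.6186
        res = corrected_resampled_ttest(
            [0.1, 0.2, 0.3], [0.0, 0.0, 0.0], n_train=100, n_test=25
        )
        assert res.t == pytest.approx(2.6186, abs=1e-3)
        assert res.df == 2
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(res.t, df=2), abs=1e-12
        )

    def test_correction_strictly_shrinks_evidence(self, rng):
        a = rng.normal(0.3, 0.1, size=20)
        b = rng.normal(0.0, 0.1, size=20)
        corrected = corrected_resampled_ttest(a, b, n_train=80, n_test=20)
        naive = stats.ttest_rel(a, b)
        assert abs(corrected.t) < abs(naive.statistic)

    def test_zero_variance_flagged(self):
        res = corrected_resampled_ttest([0.2, 0.2], [0.1, 0.1], 80, 20)
        assert res.degenerate
        assert res.p_value < 1e-300


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_decreases_and_preserves_order(self, ps):
        q = fdr_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order_p = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order_p]) >= -1e-12)


class TestLoadingReplicability:
    def test_identical_and_reversed(self):
        a = pd.Series([0.1, 0.5, 0.9, -0.2], index=list("abcd"))
        rho, _ = compare_loadings_across_samples(a, a)
        assert rho == pytest.approx(1.0)
        rho, _ = compare_loadings_across_samples(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_disjoint_names_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
        with pytest.raises(ValueError, match="share no"):
            compare_loadings_across_samples(a, b)

    def test_replication_across_independent_cohorts(self):
        # two cohorts from one generative spec must agree on loadings
        sizes = {"psqi": 3, "asr": 2, "gmv": 10, "motor": 3}
        loadings = {}
        for cohort_seed in (101, 202):
            spec = planted_spec(400, rho=0.6, seed=cohort_seed, domain_sizes=sizes)
            # uneven planted loadings so ranks are informative
            rng = np.random.default_rng(7)  # same pattern for both cohorts
            spec.x_loadings = spec.x_loadings * rng.uniform(0.2, 2.0, 15)
            bundle = generate_cohort(spec)
            model = standard_model_definitions(bundle)["psqi+asr+gmv"]
            config = ValidationConfig(
                n_outer=6, n_inner=3, grid=((0.5, 0.5),), seed=cohort_seed
            )
            _, summary = run_multiple_holdout(bundle, model, config)
            gmv = [f for f in summary.x_loadings_mean.index if f.startswith("gmv")]
            loadings[cohort_seed] = summary.x_loadings_mean.loc[gmv, "mode_1"]
        rho, p = compare_loadings_across_samples(loadings[101], loadings[202])
        assert rho > 0.5
        assert p < 0.05


class TestEffectSizes:
    def test_rank_biserial_no_effect_midpoint(self):
        assert rank_biserial_from_u(50.0, 10, 10) == 0.0

    def test_rank_biserial_out_of_range(self):
        with pytest.raises(ValueError):
            rank_biserial_from_u(101.0, 10, 10)

    def test_identical_samples_zero_effects(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        g = group_difference_stats(x, x)
        assert g.t == pytest.approx(0.0)
        assert g.cohens_d == pytest.approx(0.0)
        assert g.rank_biserial == pytest.approx(0.0)

    def test_complete_separation(self):
        g = group_difference_stats([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # exhaustive pair comparison: no x beats any y
        assert g.u == 0.0
        assert g.rank_biserial == -1.0

    def test_simulated_shift_recovers_cohens_d(self):
        rng = np.random.default_rng(55)
        x = rng.normal(0.5, 1.0, size=200)
        y = rng.normal(0.0, 1.0, size=200)
        g = group_difference_stats(x, y)
        se = np.sqrt(1 / 200 + 1 / 200 + 0.5**2 / (2 * 398))
        assert abs(g.cohens_d - 0.5) < 3 * se
        # Welch df a la Satterthwaite stays below n1 + n2 - 2
        assert g.df <= 398

    def test_double_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            g = group_difference_stats([1.0, 1.0], [1.0, 1.0])
        assert g.degenerate and np.isnan(g.cohens_d)
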