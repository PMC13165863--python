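import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dyadsense.stats import (benjamini_hochberg, cohens_d, posthoc_power,
                             t_test, run_battery)


def bh_oracle(p):
    """Literal step-up definition: q_i = min over ranks >= rank(i) of p_(j)m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for pos, i in enumerate(order):
        out[i] = min(min(p[order[k]] * m / (k + 1) for k in range(pos, m)), 1.0)
    return out


class TestCohensD:
    def test_identical_independent_samples_give_zero(self):
        es = cohens_d([1, 2, 3, 4], [1, 2, 3, 4])
        assert es.d == 0.0 and es.band == "negligible"

    def test_one_pooled_sd_apart_gives_one(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + a.std(ddof=1)
        es = cohens_d(b, a)
        assert es.d == pytest.approx(1.0)
        assert es.band == "large"

    @pytest.mark.parametrize("d,band", [
        (0.1, "negligible"), (0.2, "small"), (0.49, "small"),
        (0.5, "medium"), (0.79, "medium"), (0.8, "large"), (0.85, "large"),
        (-0.85, "large"),
    ])
    def test_interpretation_bands(self, d, band):
        from dyadsense.stats import effect_band
        assert effect_band(d) == band

    def test_sign_antisymmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d)
        assert cohens_d(a, b, "paired").d == pytest.approx(
            -cohens_d(b, a, "paired").d)

    def test_matches_independent_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1.3, 14)
        assert cohens_d(a, b).d == pytest.approx(
            float(pingouin.compute_effsize(a, b, eftype="cohen")))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError):
            cohens_d([1, 2, 3], [2, 3, 4], "paired")  # constant differences

    def test_hedges_shrinks_toward_zero(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        plain = cohens_d(a, b).d
        corrected = cohens_d(a, b, hedges=True).d
        assert abs(corrected) < abs(plain)


class TestTTest:
    def test_sample_against_itself_gives_t_zero(self):
        res = t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_paired_toy_vectors_match_reference(self):
        pingouin = pytest.importorskip("pingouin")
        a, b = [1, 2, 3, 4], [2, 3, 5, 4]
        res = t_test(a, b, "paired")
        ref = pingouin.ttest(a, b, paired=True)
        assert res.statistic == pytest.approx(float(ref["T"].iloc[0]))
        assert res.p_raw == pytest.approx(float(ref["p_val"].iloc[0]))
        assert res.df == float(ref["dof"].iloc[0])

    def test_ci_brackets_mean_difference(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        res = t_test(a, b)
        lo, hi = res.ci95
        assert lo <= a.mean() - b.mean() <= hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test([1, 2, 3, 4], [2, 3, 4, 5], "paired")

    def test_p_uniform_under_null(self):
        """KS check on 10^4 replicated null t-tests."""
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (10_000, 10))
        b = rng.normal(0, 1, (10_000, 10))
        pvals = sps.ttest_ind(a, b, axis=1).pvalue
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestBenjaminiHochberg:
    def test_hand_worked_stepup(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37]) == pytest.approx([0.37])

    def test_ties_stay_put(self):
        assert benjamini_hochberg([0.5] * 6) == pytest.approx([0.5] * 6)

    def test_adjusted_never_below_raw(self):
        p = [0.001, 0.2, 0.04, 0.9, 0.012]
        assert np.all(benjamini_hochberg(p) >= np.asarray(p))

    def test_order_preserving(self):
        p = [0.001, 0.2, 0.04, 0.9, 0.012]
        q = benjamini_hochberg(p)
        ranks_p = np.argsort(np.argsort(p))
        for i in range(len(p)):
            for j in range(len(p)):
                if ranks_p[i] < ranks_p[j]:
                    assert q[i] <= q[j]

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        p = rng.uniform(size=15)
        assert benjamini_hochberg(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1,
                    max_size=20))
    @settings(max_examples=250, derandomize=True)
    def test_matches_bruteforce_oracle(self, p):
        assert benjamini_hochberg(p) == pytest.approx(bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])


class TestPower:
    def test_null_effect_gives_alpha(self):
        for design in ("paired", "independent"):
            assert posthoc_power(0.0, 10, 0.05, design).power == \
                pytest.approx(0.05, abs=1e-10)

    def test_monotone_in_n_d_and_alpha(self):
        assert posthoc_power(1.0, 12).power > posthoc_power(1.0, 6).power
        assert posthoc_power(1.2, 8).power > posthoc_power(0.8, 8).power
        assert posthoc_power(0.8, 8, 0.10).power > \
            posthoc_power(0.8, 8, 0.05).power

    def test_converges_to_one(self):
        assert posthoc_power(0.5, 4000).power == pytest.approx(1.0, abs=1e-6)

    def test_matches_statsmodels_reference(self):
        import statsmodels.stats.power as smp
        assert posthoc_power(1.0, 6).power == pytest.approx(
            smp.TTestIndPower().power(1.0, 6, 0.05))
        assert posthoc_power(1.92, 6, design="paired").power == pytest.approx(
            smp.TTestPower().power(1.92, 6, 0.05))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power(0.5, 6, design="crossover")
        with pytest.raises(ValueError):
            posthoc_power(0.5, 1)
        with pytest.raises(ValueError):
            posthoc_power(0.5, 6, alpha=1.5)


class TestBattery:
    def test_tidy_output_with_adjusted_p(self):
        rng = np.random.default_rng(6)
        comparisons = {
            "pre_vs_post": (rng.normal(0, 1, 12), rng.normal(1, 1, 12),
                            "paired"),
            "train_vs_control": (rng.normal(0, 1, 12), rng.normal(0.2, 1, 12),
                                 "independent"),
        }
        frame = run_battery(comparisons)
        assert list(frame["comparison"]) == list(comparisons)
        assert np.all(frame["p_adj"] >= frame["p_raw"])
        assert set(frame["band"]) <= {"negligible", "small", "medium", "large"}
        assert np.all((frame["power"] >= 0) & (frame["power"] <= 1))
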