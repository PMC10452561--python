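"""Two-sample MR estimators: harmonization, closed-form identities, robustness."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from aim_mr.datatypes import EstimatorError, HarmonizationError
from aim_mr.mr import (
    cochran_q,
    egger,
    harmonize,
    ivw,
    radial_filter,
    scatter_funnel_data,
    weighted_median,
)
from tests.conftest import make_summary_stats, make_two_sample_stats


class TestHarmonize:
    def _pair(self, ea_o, oa_o, beta_o=0.3, eaf_o=0.2, ea_e="A", oa_e="G"):
        exp = make_summary_stats(["v1"], [1.0], [0.1], effect_allele=ea_e, other_allele=oa_e)
        out = make_summary_stats(
            ["v1"], [beta_o], [0.1], eaf=[eaf_o], effect_allele=ea_o, other_allele=oa_o
        )
        return exp, out

    def test_same_alleles_untouched(self):
        h = harmonize(*self._pair("A", "G"))
        assert h.data.loc[0, "beta_outcome"] == 0.3
        assert h.data.loc[0, "action"] == "kept"

    def test_swapped_alleles_flip_sign_and_eaf(self):
        h = harmonize(*self._pair("G", "A"))
        assert h.data.loc[0, "beta_outcome"] == -0.3
        assert h.data.loc[0, "eaf_outcome"] == pytest.approx(0.8)
        assert h.data.loc[0, "action"] == "flipped"

    def test_palindromic_dropped_under_strict_policy(self):
        exp, out = self._pair("A", "T", ea_e="A", oa_e="T")
        h = harmonize(exp, out, "drop")
        assert h.n_instruments == 0
        assert list(h.audit["action"]) == ["removed-palindromic"]

    def test_palindromic_maf_window_policy(self):
        exp = make_summary_stats(["v1"], [1.0], [0.1], eaf=[0.1], effect_allele="C", other_allele="G")
        out = make_summary_stats(["v1"], [0.2], [0.1], eaf=[0.12], effect_allele="C", other_allele="G")
        assert harmonize(exp, out, "maf").n_instruments == 1
        out_hi = make_summary_stats(["v1"], [0.2], [0.1], eaf=[0.45], effect_allele="C", other_allele="G")
        assert harmonize(exp, out_hi, "maf").n_instruments == 0

    def test_incompatible_alleles_removed(self):
        h = harmonize(*self._pair("A", "C"))
        assert h.n_instruments == 0
        assert list(h.audit["action"]) == ["removed-incompatible"]

    def test_zero_exposure_beta_removed(self):
        exp = make_summary_stats(["v1", "v2"], [0.0, 1.0], [0.1, 0.1])
        out = make_summary_stats(["v1", "v2"], [0.3, 0.3], [0.1, 0.1])
        h = harmonize(exp, out)
        assert list(h.data["variant"]) == ["v2"]

    def test_no_shared_variants_raises(self):
        exp = make_summary_stats(["v1"], [1.0], [0.1])
        out = make_summary_stats(["v2"], [1.0], [0.1])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        exp = make_summary_stats(["v1"], [2.0], [0.1])
        out = make_summary_stats(["v1"], [0.5], [0.2])
        res = ivw(harmonize(exp, out), allow_single=True)
        assert res.estimate == pytest.approx(0.25)
        with pytest.raises(EstimatorError):
            ivw(harmonize(exp, out))

    def test_homogeneous_ratios(self):
        exp = make_summary_stats(["a", "b", "c"], [1.0, 2.0, 4.0], [0.1] * 3)
        out = make_summary_stats(["a", "b", "c"], [0.5, 1.0, 2.0], [0.1] * 3)
        res = ivw(harmonize(exp, out))
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-12)
        assert res.q_p == pytest.approx(1.0)

    def test_equals_wls_through_origin_oracle(self):
        rng = np.random.default_rng(0)
        exp, out = make_two_sample_stats(rng, 50, theta=0.3, pleiotropy_sd=0.02)
        h = harmonize(exp, out)
        res = ivw(h)
        bx = h.data["beta_exposure"].to_numpy()
        by = h.data["beta_outcome"].to_numpy()
        w = 1.0 / h.data["se_outcome"].to_numpy() ** 2
        oracle = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert res.estimate == pytest.approx(oracle, abs=1e-10)

    def test_ci_and_or_consistency(self):
        rng = np.random.default_rng(1)
        exp, out = make_two_sample_stats(rng, 20, theta=0.1)
        res = ivw(harmonize(exp, out))
        assert res.ci_low == pytest.approx(res.estimate - 1.959963984540054 * res.se)
        o, lo, hi = res.odds_ratio()
        assert lo < o < hi
        assert o == pytest.approx(np.exp(res.estimate))


class TestCochranQ:
    def test_two_instrument_hand_arithmetic(self):
        # ratios (0, 1), equal weights 1 -> IVW estimate 0.5, Q = 0.5
        exp = make_summary_stats(["a", "b"], [1.0, 1.0], [0.1, 0.1])
        out = make_summary_stats(["a", "b"], [0.0, 1.0], [1.0, 1.0])
        h = harmonize(exp, out)
        res = ivw(h)
        assert res.estimate == pytest.approx(0.5)
        q, df, p = cochran_q(h, res.estimate)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert df == 1

    def test_null_calibration(self):
        """Q/df near 1 and p roughly uniform when ratios are homogeneous + noise."""
        rng = np.random.default_rng(2)
        qdfs, pvals = [], []
        for _ in range(100):
            exp, out = make_two_sample_stats(rng, 30, theta=0.2, pleiotropy_sd=0.0)
            h = harmonize(exp, out)
            res = ivw(h)
            qdfs.append(res.cochran_q / res.q_df)
            pvals.append(res.q_p)
        assert np.mean(qdfs) == pytest.approx(1.0, abs=0.15)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestEgger:
    def test_exact_linear_recovery(self):
        bx = np.array([1.0, 2.0, 3.0, 4.0])
        a, theta = 0.05, 0.4
        exp = make_summary_stats(list("abcd"), bx, [0.1] * 4)
        out = make_summary_stats(list("abcd"), a + theta * bx, [0.1] * 4)
        res = egger(harmonize(exp, out))
        assert res.estimate == pytest.approx(theta, abs=1e-12)
        assert res.egger_intercept == pytest.approx(a, abs=1e-12)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(3)
        exp, out = make_two_sample_stats(rng, 50, theta=0.25, pleiotropy_sd=0.03)
        h = harmonize(exp, out)
        res = egger(h)
        sign = np.sign(h.data["beta_exposure"].to_numpy())
        bx = h.data["beta_exposure"].to_numpy() * sign
        by = h.data["beta_outcome"].to_numpy() * sign
        w = 1.0 / h.data["se_outcome"].to_numpy() ** 2
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert res.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_intercept_null_calibration(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            exp, out = make_two_sample_stats(rng, 30, theta=0.2)
            pvals.append(egger(harmonize(exp, out)).egger_intercept_p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_instruments(self):
        exp = make_summary_stats(["a", "b"], [1.0, 2.0], [0.1, 0.1])
        out = make_summary_stats(["a", "b"], [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(EstimatorError):
            egger(harmonize(exp, out))


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        exp = make_summary_stats(list("abc"), [1.0, 1.0, 1.0], [0.1] * 3)
        out = make_summary_stats(list("abc"), [1.0, 2.0, 3.0], [1.0] * 3)
        res = weighted_median(harmonize(exp, out), n_boot=200, seed=0)
        assert res.estimate == pytest.approx(2.0)

    def test_concentrated_weight_picks_that_ratio(self):
        exp = make_summary_stats(list("abc"), [1.0, 1.0, 1.0], [0.1] * 3)
        out = make_summary_stats(list("abc"), [1.0, 2.0, 3.0], [1e-4, 10.0, 10.0])
        res = weighted_median(harmonize(exp, out), n_boot=200, seed=0)
        assert res.estimate == pytest.approx(1.0, abs=0.01)

    def test_robust_to_30pct_invalid_instruments(self):
        """Weighted median stays closer to the truth than IVW under contamination."""
        rng = np.random.default_rng(5)
        theta = 0.3
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            m = 30
            bx = rng.uniform(0.5, 2.0, m)
            sx = np.full(m, 0.03)
            by = theta * bx + rng.normal(0, 0.05, m)
            bad = rng.choice(m, size=9, replace=False)  # 30% invalid
            by[bad] += rng.uniform(0.5, 1.0, 9)  # strong directional pleiotropy
            ids = [f"v{i}" for i in range(m)]
            exp = make_summary_stats(ids, bx, sx)
            out = make_summary_stats(ids, by, np.full(m, 0.05))
            h = harmonize(exp, out)
            wm = weighted_median(h, n_boot=120, seed=int(rng.integers(1 << 30)))
            iv = ivw(h)
            wins += abs(wm.estimate - theta) < abs(iv.estimate - theta)
        assert wins / n_rep >= 0.9

    def test_small_bootstrap_warns(self):
        exp = make_summary_stats(list("abc"), [1.0, 1.0, 1.0], [0.1] * 3)
        out = make_summary_stats(list("abc"), [1.0, 2.0, 3.0], [1.0] * 3)
        with pytest.warns(UserWarning):
            weighted_median(harmonize(exp, out), n_boot=50, seed=0)


class TestRadial:
    def test_homogeneous_no_outliers(self):
        exp = make_summary_stats(list("abcd"), [1.0, 2.0, 3.0, 4.0], [0.1] * 4)
        out = make_summary_stats(list("abcd"), [0.5, 1.0, 1.5, 2.0], [0.1] * 4)
        rad = radial_filter(harmonize(exp, out))
        assert rad.table["outlier"].sum() == 0
        assert len(rad.retained) == 4

    def test_displaced_instrument_flagged(self):
        rng = np.random.default_rng(6)
        exp, out = make_two_sample_stats(rng, 30, theta=0.3)
        out.loc[0, "beta"] += 10 * out.loc[0, "se"]  # 10-SE displacement
        rad = radial_filter(harmonize(exp, out))
        assert rad.table.loc[rad.table["variant"] == "rs0000", "outlier"].item()
        assert "rs0000" not in rad.retained

    def test_q_contributions_sum_to_global_q(self):
        rng = np.random.default_rng(7)
        exp, out = make_two_sample_stats(rng, 50, theta=0.2, pleiotropy_sd=0.05)
        h = harmonize(exp, out)
        rad = radial_filter(h)
        res = ivw(h)
        assert rad.table["q_i"].sum() == pytest.approx(rad.global_q, abs=1e-8)
        assert rad.global_q == pytest.approx(res.cochran_q, abs=1e-8)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(flips=st.lists(st.booleans(), min_size=5, max_size=5))
def test_estimates_invariant_under_joint_sign_flip(flips):
    """Flipping both betas of any instrument leaves IVW and Egger unchanged."""
    rng = np.random.default_rng(8)
    exp, out = make_two_sample_stats(rng, 5, theta=0.4, pleiotropy_sd=0.02)
    h0 = harmonize(exp, out)
    exp_f, out_f = exp.copy(), out.copy()
    sign = np.where(np.array(flips), -1.0, 1.0)
    exp_f["beta"] *= sign
    out_f["beta"] *= sign
    h1 = harmonize(exp_f, out_f)
    assert ivw(h1).estimate == pytest.approx(ivw(h0).estimate, abs=1e-10)
    assert egger(h1).estimate == pytest.approx(egger(h0).estimate, abs=1e-10)
    assert egger(h1).egger_intercept == pytest.approx(egger(h0).egger_intercept, abs=1e-10)


class TestScatterFunnel:
    def test_tables_match_estimators(self):
        rng = np.random.default_rng(9)
        exp, out = make_two_sample_stats(rng, 20, theta=0.3)
        h = harmonize(exp, out)
        results = [ivw(h), egger(h)]
        tables = scatter_funnel_data(h, results)
        assert len(tables["scatter"]) == 20
        assert len(tables["funnel"]) == 20
        r, s = h.ratios()
        assert np.allclose(tables["funnel"]["ratio"], r)
        assert set(tables["scatter_lines"]["method"]) == {"ivw", "egger"}

    def test_empty_set_errors(self):
        h = harmonize(
            make_summary_stats(["v1"], [1.0], [0.1], effect_allele="A", other_allele="T"),
            make_summary_stats(["v1"], [0.1], [0.1], effect_allele="A", other_allele="T"),
            "drop",
        )
        with pytest.raises(EstimatorError):
            scatter_funnel_data(h, [])
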