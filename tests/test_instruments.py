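"""GWAS scans, explained variance, LD pruning, exclusion/Steiger filters, F stats."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from aim_mr.datatypes import EstimatorError
from aim_mr.instruments import (
    FilterLog,
    ancestry_gwas,
    exclusion_filter,
    explained_variance,
    instrument_strength,
    ld_prune,
    mean_f_statistic,
    outcome_gwas,
    steiger_filter,
)
from tests.conftest import make_summary_stats


class TestAncestryGwas:
    def test_perfect_linear_relation(self, genotypes_from_dosage):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(100, 3))
        g = genotypes_from_dosage(dosage)
        exposure = 10.0 * dosage[:, 1]
        res = ancestry_gwas(g, exposure)
        assert res.loc[1, "beta"] == pytest.approx(10.0, abs=1e-10)
        assert res.loc[1, "p"] < 1e-100

    def test_matches_statsmodels_full_model(self, genotypes_from_dosage):
        """FWL residualization equals the full OLS fit per variant."""
        rng = np.random.default_rng(1)
        n = 200
        dosage = rng.integers(0, 3, size=(n, 5))
        age = rng.uniform(30, 70, n)
        sex = rng.integers(0, 2, n)
        y = 40 + 0.5 * dosage[:, 2] + 0.1 * age + sex + rng.normal(0, 2, n)
        res = ancestry_gwas(genotypes_from_dosage(dosage), y, age=age, sex=sex)
        for j in range(5):
            x = sm.add_constant(
                np.column_stack([dosage[:, j].astype(float), age, sex])
            )
            fit = sm.OLS(y, x).fit()
            assert res.loc[j, "beta"] == pytest.approx(fit.params[1], rel=1e-9)
            assert res.loc[j, "se"] == pytest.approx(fit.bse[1], rel=1e-9)
            assert res.loc[j, "p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_monomorphic_flagged(self, genotypes_from_dosage):
        dosage = np.column_stack(
            [np.full(50, 2), np.random.default_rng(2).integers(0, 3, 50)]
        )
        res = ancestry_gwas(genotypes_from_dosage(dosage), np.random.default_rng(3).normal(size=50))
        assert res.loc[0, "flag"] == "monomorphic"
        assert res.loc[0, "se"] == np.inf and res.loc[0, "p"] == 1.0

    def test_null_p_values_uniform(self, genotypes_from_dosage):
        """Permuted exposure gives uniform p-values across variants."""
        rng = np.random.default_rng(4)
        n, m = 2000, 500
        dosage = rng.binomial(2, 0.3, size=(n, m))
        exposure = rng.permutation(rng.normal(50, 10, n))
        res = ancestry_gwas(genotypes_from_dosage(dosage), exposure)
        assert sps.kstest(res["p"], "uniform").pvalue > 0.01

    def test_beta_equivariance_under_exposure_rescaling(self, genotypes_from_dosage):
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, 0.4, size=(120, 4))
        y = dosage @ rng.normal(size=4) + rng.normal(size=120)
        r1 = ancestry_gwas(genotypes_from_dosage(dosage), y)
        r2 = ancestry_gwas(genotypes_from_dosage(dosage), 100.0 * y)
        assert np.allclose(r2["beta"], 100.0 * r1["beta"])
        assert np.allclose(r2["p"], r1["p"], atol=1e-12)

    def test_rank_deficient_covariates_rejected(self, genotypes_from_dosage):
        dosage = np.random.default_rng(6).binomial(2, 0.5, size=(60, 2))
        age = np.random.default_rng(7).uniform(30, 60, 60)
        with pytest.raises(EstimatorError, match="rank"):
            ancestry_gwas(
                genotypes_from_dosage(dosage),
                np.random.default_rng(8).normal(size=60),
                age=age,
                pcs=np.column_stack([age, age]),
            )


class TestOutcomeGwas:
    def test_logistic_matches_statsmodels(self, genotypes_from_dosage):
        rng = np.random.default_rng(10)
        n = 600
        dosage = rng.binomial(2, 0.35, size=(n, 8))
        age = rng.uniform(30, 70, n)
        sex = rng.integers(0, 2, n)
        from scipy.special import expit

        y = rng.binomial(1, expit(-1 + 0.3 * dosage[:, 0] + 0.01 * age))
        res = outcome_gwas(genotypes_from_dosage(dosage), y, age=age, sex=sex)
        for j in range(8):
            x = sm.add_constant(np.column_stack([dosage[:, j].astype(float), age, sex]))
            fit = sm.Logit(y, x).fit(disp=0)
            assert res.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-6)
            assert res.loc[j, "se"] == pytest.approx(fit.bse[1], rel=1e-4)

    def test_separation_flagged(self, genotypes_from_dosage):
        dosage = np.repeat([0, 2], 40)[:, None]
        y = (dosage[:, 0] > 0).astype(int)
        res = outcome_gwas(genotypes_from_dosage(dosage), y)
        assert res.loc[0, "flag"] == "separation"

    def test_log_or_recovery(self, genotypes_from_dosage):
        """Mean estimated log-OR over replicates recovers the simulated 0.2."""
        from scipy.special import expit

        betas = []
        for rep in range(60):
            rng = np.random.default_rng(200 + rep)
            dosage = rng.binomial(2, 0.3, size=(2000, 1))
            y = rng.binomial(1, expit(-1.0 + 0.2 * dosage[:, 0]))
            res = outcome_gwas(genotypes_from_dosage(dosage), y)
            betas.append(res.loc[0, "beta"])
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert np.mean(betas) == pytest.approx(0.2, abs=4 * mc_se)

    def test_null_rejection_rate_within_binomial_envelope(self, genotypes_from_dosage):
        rng = np.random.default_rng(11)
        n, m = 1500, 500
        dosage = rng.binomial(2, 0.4, size=(n, m))
        y = rng.binomial(1, 0.3, size=n)
        res = outcome_gwas(genotypes_from_dosage(dosage), y)
        rate = float((res["p"] < 0.05).mean())
        lo, hi = sps.binom.interval(0.99, m, 0.05)
        assert lo / m <= rate <= hi / m


class TestExplainedVariance:
    @pytest.mark.parametrize(
        "beta, maf, expected",
        [(0.0, 0.3, 0.0), (0.1, 0.5, 0.005), (0.2, 0.1, 0.0072)],
    )
    def test_arithmetic(self, beta, maf, expected):
        assert explained_variance(beta, maf) == pytest.approx(expected, abs=1e-12)

    def test_maf_domain(self):
        with pytest.raises(ValueError):
            explained_variance(0.1, 0.7)


class TestLdPrune:
    def test_enumerable_three_variant_case(self, genotypes_from_dosage):
        rng = np.random.default_rng(20)
        a = rng.binomial(2, 0.5, 500)
        c = rng.binomial(2, 0.5, 500)
        g = genotypes_from_dosage(np.column_stack([a, a, c]), ["v1", "v2", "v3"])
        kept = ld_prune(g, ["v1", "v2", "v3"], r2_threshold=0.01)
        assert kept == ["v1", "v3"]

    def test_duplicate_keeps_higher_priority_copy(self, genotypes_from_dosage):
        rng = np.random.default_rng(21)
        a = rng.binomial(2, 0.5, 300)
        g = genotypes_from_dosage(np.column_stack([a, a]), ["big", "small"])
        assert ld_prune(g, ["big", "small"], 0.5) == ["big"]

    def test_independent_variants_mostly_retained(self, genotypes_from_dosage):
        rng = np.random.default_rng(22)
        dosage = rng.binomial(2, 0.5, size=(5000, 40))
        ids = [f"v{j}" for j in range(40)]
        kept = ld_prune(genotypes_from_dosage(dosage, ids), ids, 0.01)
        assert len(kept) >= 35  # exclusions only from sampling noise

    def test_deterministic_given_ranking(self, genotypes_from_dosage):
        rng = np.random.default_rng(23)
        dosage = rng.binomial(2, 0.5, size=(400, 20))
        ids = [f"v{j}" for j in range(20)]
        g = genotypes_from_dosage(dosage, ids)
        assert ld_prune(g, ids, 0.05) == ld_prune(g, ids, 0.05)

    def test_unknown_variant_raises(self, genotypes_from_dosage):
        g = genotypes_from_dosage(np.zeros((10, 1), dtype=int), ["v1"])
        with pytest.raises(KeyError):
            ld_prune(g, ["v1", "ghost"], 0.1)


class TestExclusionFilter:
    def _stats(self):
        return make_summary_stats(["a", "b", "c"], [1, 1, 1], [0.1, 0.1, 0.1])

    def test_empty_list_is_identity(self):
        kept, dropped = exclusion_filter(self._stats(), None, 5e-8)
        assert len(kept) == 3 and len(dropped) == 0

    def test_threshold_behaviour(self):
        excl = pd.DataFrame(
            {"variant": ["a", "b"], "trait": ["gallstones", "smoking"], "p": [1e-9, 1e-7]}
        )
        kept, dropped = exclusion_filter(self._stats(), excl, 5e-8)
        assert list(kept["variant"]) == ["b", "c"]  # 1e-7 survives at 5e-8
        kept2, _ = exclusion_filter(self._stats(), excl, 5e-6)
        assert list(kept2["variant"]) == ["c"]  # stricter sensitivity threshold


class TestSteiger:
    def test_trivial_directionality(self):
        exp = make_summary_stats(["a", "b"], [1.0, 0.01], [0.05, 0.05], n=10000)
        out = make_summary_stats(["a", "b"], [0.01, 1.0], [0.05, 0.05], n=10000)
        kept, diag = steiger_filter(exp, out, outcome_binary=False)
        assert kept == ["a"]
        assert diag.loc[diag["variant"] == "b", "retained"].item() == False  # noqa: E712

    def test_null_outcome_rarely_fires(self):
        """Under a null outcome the filter retains nearly all instruments."""
        rng = np.random.default_rng(30)
        total, kept_n = 0, 0
        for _ in range(200):
            m = 30
            bx = rng.uniform(1.0, 3.0, m)
            sx = np.full(m, 0.05)
            by = rng.normal(0, 0.05, m)  # no outcome signal
            exp = make_summary_stats([f"v{i}" for i in range(m)], bx, sx, n=2000)
            out = make_summary_stats([f"v{i}" for i in range(m)], by, np.full(m, 0.05), n=2000)
            kept, _ = steiger_filter(exp, out, outcome_binary=False)
            total += m
            kept_n += len(kept)
        assert kept_n / total >= 0.99

    def test_binary_requires_case_fraction(self):
        exp = make_summary_stats(["a"], [1.0], [0.1])
        out = make_summary_stats(["a"], [0.1], [0.1])
        with pytest.raises(ValueError):
            steiger_filter(exp, out, outcome_binary=True)


class TestInstrumentStrength:
    def test_arithmetic(self):
        assert instrument_strength(0.0, 100, 5) == 0.0
        assert instrument_strength(0.5, 103, 1) == pytest.approx(101.0)
        with pytest.raises(ValueError):
            instrument_strength(1.0, 100, 5)
        with pytest.raises(ValueError):
            instrument_strength(0.5, 3, 5)

    def test_mean_f_equals_mean_squared_t(self):
        rng = np.random.default_rng(31)
        beta = rng.normal(0, 1, 50)
        se = rng.uniform(0.1, 0.5, 50)
        stats_df = make_summary_stats([f"v{i}" for i in range(50)], beta, se)
        assert mean_f_statistic(stats_df) == pytest.approx(
            float(np.mean((beta / se) ** 2)), rel=1e-12
        )


class TestFilterLog:
    def test_counts_reconcile_and_never_increase(self):
        log = FilterLog()
        log.add("a", 0.1, 100, 50)
        log.add("b", 0.2, 50, 50)
        with pytest.raises(ValueError):
            log.add("c", 0.3, 50, 60)
        with pytest.raises(ValueError):
            log.add("d", 0.4, 49, 10)  # input does not match previous output
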