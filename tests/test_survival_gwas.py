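from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import survgxe as sg
from survgxe.containers import GenotypeMatrix, VariantRecord
from survgxe.survival_gwas import _spa_two_sided

from conftest import make_survival_frame


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional HWE distribution."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = (2 * n - rare - h) // 2
        probs[h] = Fraction(factorial(n) * 2**h,
                            factorial(hr) * factorial(h) * factorial(hc))
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert sg.hwe_exact_test(0, 0, 100) == 1.0
        assert sg.hwe_exact_test(100, 0, 0) == 1.0

    def test_no_heterozygotes_matches_enumeration(self):
        assert sg.hwe_exact_test(100, 0, 100) == pytest.approx(
            hwe_enumeration_oracle(100, 0, 100), rel=1e-10)

    def test_matches_enumeration_for_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            counts = (n - n_aa - n_ab, n_ab, n_aa)
            assert sg.hwe_exact_test(*counts) == pytest.approx(
                hwe_enumeration_oracle(*counts), rel=1e-9), counts

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.integers(0, 120), st.integers(0, 120), st.integers(0, 120))
    def test_property_valid_probability_and_enumeration_agreement(self, a, b, c):
        if a + b + c == 0:
            return
        p = sg.hwe_exact_test(a, b, c)
        assert 0.0 < p <= 1.0
        if a + b + c <= 80:  # keep the rational-arithmetic oracle cheap
            assert p == pytest.approx(hwe_enumeration_oracle(a, b, c), rel=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sg.hwe_exact_test(-1, 0, 5)
        with pytest.raises(ValueError):
            sg.hwe_exact_test(0, 0, 0)


def _toy_genotypes():
    """Six variants: one violating each QC filter, one clean."""
    rng = np.random.default_rng(1)
    n = 400
    clean = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
    variants = [
        VariantRecord("1", 1000, "v_lowinfo", "A", "G", info=0.1),
        VariantRecord("1", 2000, "v_multi", "A", "G,T"),
        VariantRecord("1", 3000, "v_rare", "A", "G"),
        VariantRecord("1", 4000, "v_miss", "A", "G"),
        VariantRecord("1", 5000, "v_hwe", "A", "G"),
        VariantRecord("1", 6000, "v_clean", "A", "G"),
    ]
    clean[:, 2] = 0.0
    clean[0, 2] = 1.0  # MAF 1/800 = 0.00125 >= 0.001? use 0 copies -> below
    clean[:, 2] = 0.0
    clean[: n // 2, 3] = np.nan  # 50% missing
    clean[:, 4] = 1.0  # all heterozygous: gross HWE violation
    return GenotypeMatrix(clean, variants)


class TestVariantQc:
    def test_filter_attribution_in_declared_order(self):
        genos = _toy_genotypes()
        out, report = sg.variant_qc(genos)
        assert report.variant_removals == {
            "info": 1, "biallelic": 1, "maf": 1, "missingness": 1, "hwe": 1}
        assert [v.id for v in out.variants] == ["v_clean"]
        assert report.check_totals()

    def test_clean_matrix_unchanged(self):
        spec = sg.SimulationSpec(n_samples=500, n_variants=20, seed=3,
                                 maf_range=(0.1, 0.5))
        genos = sg.simulate_genotypes(spec)
        out, report = sg.variant_qc(genos)
        assert out.n_variants == 20
        assert sum(report.variant_removals.values()) == 0
        np.testing.assert_array_equal(out.dosages, genos.dosages)

    def test_all_removed_raises(self):
        genos = _toy_genotypes().take_variants([0])
        with pytest.raises(ValueError, match="all variants removed"):
            sg.variant_qc(genos)

    def test_dosage_rounding_half_to_even(self):
        g = GenotypeMatrix(np.array([[0.5], [1.5], [0.49], [1.51]]),
                           [VariantRecord("1", 1, "v", "A", "G")])
        np.testing.assert_array_equal(g.hard_calls().ravel(), [0.0, 2.0, 0.0, 2.0])


class TestPruneRelatives:
    def test_no_pairs_keeps_all(self):
        assert sg.prune_relatives([], ["a", "b"]) == ["a", "b"]

    def test_one_pair_removes_exactly_one_deterministically(self):
        kept1 = sg.prune_relatives([("a", "b", 0.25)], ["a", "b", "c"], seed=0)
        kept2 = sg.prune_relatives([("a", "b", 0.25)], ["a", "b", "c"], seed=0)
        assert kept1 == kept2
        assert len(kept1) == 2 and "c" in kept1

    def test_below_cutoff_pairs_ignored(self):
        kept = sg.prune_relatives([("a", "b", 0.01)], ["a", "b"], seed=0)
        assert kept == ["a", "b"]

    def test_chain_resolution(self):
        # if B is removed at the first pair, the B-C pair is already broken
        # and both A and C survive; otherwise a second removal happens
        outcomes = set()
        for seed in range(20):
            kept = tuple(sg.prune_relatives([("A", "B", 0.3), ("B", "C", 0.3)],
                                            ["A", "B", "C"], seed=seed))
            assert kept in {("A", "C"), ("B",), ("C",)}
            outcomes.add(kept)
        assert ("A", "C") in outcomes

    def test_excessive_relatives_removed_first(self):
        samples = [f"s{i}" for i in range(15)]
        pairs = [("s0", f"s{i}", 0.3) for i in range(1, 13)]  # s0 in 12 pairs
        kept = sg.prune_relatives(pairs, samples, seed=1)
        assert "s0" not in kept
        assert set(samples[1:]) <= set(kept)

    def test_unknown_id_raises(self):
        with pytest.raises(ValueError, match="unknown sample"):
            sg.prune_relatives([("a", "zz", 0.3)], ["a", "b"])


def _null_fit_from(df, terms=("x1", "x2")):
    return sg.fit_cox(df, list(terms))


class TestScoreTest:
    def test_zero_residuals_give_null_score(self):
        rng = np.random.default_rng(2)
        df = make_survival_frame(50, rng)
        fit = _null_fit_from(df)
        fit.martingale_residuals = np.zeros(fit.n)
        res = sg.score_test(rng.binomial(2, 0.3, fit.n).astype(float), fit)
        assert res.score == 0.0
        assert res.p_spa == 1.0

    def test_zero_variance_dosage_non_testable(self):
        rng = np.random.default_rng(3)
        df = make_survival_frame(50, rng)
        fit = _null_fit_from(df)
        res = sg.score_test(np.ones(fit.n), fit)
        assert res.method_used == "non_testable"
        assert np.isnan(res.p_spa)

    def test_spa_close_to_normal_when_skew_small(self):
        """With ~50% events and a common variant the score distribution is
        near-Gaussian, so SPA and normal p agree within 25%."""
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(200):
            df = make_survival_frame(2000, rng,
                                     betas={"x1": 0, "x2": 0, "x3": 0},
                                     censor_scale=1.0)
            fit = _null_fit_from(df)
            g = rng.binomial(2, 0.4, fit.n).astype(float)
            res = sg.score_test(g, fit)
            if res.method_used == "spa":
                assert 0.8 < res.p_spa / res.p_normal < 1.25
                checked += 1
            if checked >= 5:
                break
        assert checked >= 5

    def test_spa_monotone_in_score_magnitude(self):
        rng = np.random.default_rng(9)
        df = make_survival_frame(300, rng, censor_scale=0.3)
        fit = _null_fit_from(df)
        r = fit.martingale_residuals
        V = 100.0
        ps = [_spa_two_sided(s, V, 0.2, r) for s in np.linspace(25, 120, 12)]
        assert all(p is not None for p in ps)
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_mean_imputation_balanced_missingness_preserves_score(self):
        """When the two masked samples carry equal-magnitude opposite-sign
        residuals and their true dosages equal the observed mean, mean
        imputation reproduces the complete-data score exactly."""
        rng = np.random.default_rng(10)
        df = make_survival_frame(60, rng)
        fit = sg.fit_cox(df, [])  # null model: residualization = centering
        r = fit.martingale_residuals
        i, j = int(np.argmax(r)), int(np.argmin(r))
        r[j] = -r[i]  # enforce exact sign balance for the constructed check
        g = rng.binomial(2, 0.4, fit.n).astype(float)
        mean_rest = g[[k for k in range(fit.n) if k not in (i, j)]].mean()
        g[[i, j]] = mean_rest
        g_missing = g.copy()
        g_missing[[i, j]] = np.nan
        s_complete = sg.score_test(g, fit).score
        s_imputed = sg.score_test(g_missing, fit).score
        assert s_imputed == pytest.approx(s_complete, abs=1e-10)


class TestRunGwas:
    def test_subgroup_uses_stratum_samples_only(self, small_sim):
        _, genos, cohort = small_sim
        res = sg.run_gwas(genos, cohort, subgroup=("fos", 1.0))
        assert (res["n"] == int((cohort["fos"] == 1.0).sum())).all()

    def test_subgroup_without_events_raises(self, small_sim):
        _, genos, cohort = small_sim
        cohort = cohort.copy()
        cohort.loc[cohort["fos"] == 1.0, "event_dementia"] = 0
        with pytest.raises(ValueError, match="no events"):
            sg.run_gwas(genos, cohort, subgroup=("fos", 1.0))

    def test_planted_main_effect_detected(self):
        spec = sg.SimulationSpec(
            n_samples=8000, n_variants=10, seed=30, maf_range=(0.3, 0.3),
            baseline_hazard_rate=0.012,
            causal_effects=[(4, 0.5, 0.0)])
        genos = sg.simulate_genotypes(spec)
        cohort = sg.simulate_cohort(spec, genos)
        res = sg.run_gwas(genos, cohort)
        assert res.loc[res["id"] == "snp4", "p_spa"].iloc[0] < 1e-6
        assert res["p_spa"].idxmin() == 4

    def test_summary_stats_roundtrip(self, small_sim, tmp_path):
        from survgxe import dataio

        _, genos, cohort = small_sim
        out = tmp_path / "gwas.tsv"
        res = sg.run_gwas(genos, cohort, out=str(out))
        back = dataio.read_summary_stats(out)
        assert list(back.columns) == list(res.columns)
        assert len(back) == genos.n_variants


class TestGenomicInflation:
    def test_null_z_near_one(self):
        rng = np.random.default_rng(5)
        lam = sg.genomic_inflation(rng.standard_normal(100_000))
        assert abs(lam - 1.0) < 0.03

    def test_scaling(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(10_000)
        assert sg.genomic_inflation(2 * z) == pytest.approx(
            4 * sg.genomic_inflation(z))

    def test_too_few_results_raises(self):
        with pytest.raises(ValueError):
            sg.genomic_inflation(np.ones(10))
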