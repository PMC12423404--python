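import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import survgxe as sg


def _gwas_table(ids, ps, af=0.3):
    n = len(ids)
    return pd.DataFrame({
        "chrom": ["1"] * n, "pos": np.arange(1, n + 1) * 10_000, "id": ids,
        "ref": ["A"] * n, "alt": ["G"] * n, "af": [af] * n,
        "n": 100, "n_events": 10, "score": 0.0, "z": 0.0,
        "p_normal": ps, "p_spa": ps, "method": "normal",
    })


class TestSelectCandidates:
    def test_subgroup_only_hit_selected_with_source(self):
        ids = ["a", "b", "c"]
        overall = _gwas_table(ids, [0.5, 0.5, 0.5])
        users = _gwas_table(ids, [1e-6, 0.5, 0.5])
        nonusers = _gwas_table(ids, [0.5, 0.5, 0.5])
        sel = sg.select_candidates(overall, users, nonusers)
        assert sel["id"].tolist() == ["a"]
        assert sel["sources"].iloc[0] == "users"

    def test_low_maf_excluded_despite_tiny_p(self):
        ids = ["a", "b"]
        overall = _gwas_table(ids, [1e-9, 1e-9])
        overall.loc[0, "af"] = 0.005  # MAF 0.005 <= 0.01
        sel = sg.select_candidates(overall, _gwas_table(ids, [1, 1]),
                                   _gwas_table(ids, [1, 1]))
        assert sel["id"].tolist() == ["b"]

    def test_multiple_sources_tagged(self):
        ids = ["a"]
        sel = sg.select_candidates(_gwas_table(ids, [1e-6]),
                                   _gwas_table(ids, [1e-7]),
                                   _gwas_table(ids, [0.9]))
        assert sel["sources"].iloc[0] == "overall,users"
        assert sel["p_min"].iloc[0] == pytest.approx(1e-7)

    def test_all_null_gives_empty_set(self):
        ids = ["a", "b"]
        null = _gwas_table(ids, [0.3, 0.7])
        assert sg.select_candidates(null, null, null).empty


class TestBonferroni:
    def test_threshold_values(self):
        assert sg.bonferroni_threshold(1) == 0.05
        assert sg.bonferroni_threshold(50) == pytest.approx(1e-3)
        assert sg.bonferroni_threshold(178) == pytest.approx(0.05 / 178)
        with pytest.raises(ValueError):
            sg.bonferroni_threshold(0)


def binomial_two_sided_oracle(k, n):
    """Exact-rational enumeration of the two-sided binomial test at p=1/2."""
    pmf = [Fraction(math.comb(n, i), 2**n) for i in range(n + 1)]
    return float(sum(p for p in pmf if p <= pmf[k]))


class TestSubgroupPreference:
    @pytest.mark.parametrize("k,n,expected", [
        (13, 15, 0.0074), (12, 15, 0.035)])
    def test_reported_values_to_two_sf(self, k, n, expected):
        p = sg.subgroup_preference_test(k, n)
        assert float(f"{p:.2g}") == expected

    def test_all_in_one_subgroup_closed_form(self):
        assert sg.subgroup_preference_test(15, 15) == pytest.approx(2 * 0.5**15)

    def test_matches_enumeration_for_all_small_n(self):
        for n in range(1, 31):
            for k in range(n + 1):
                assert sg.subgroup_preference_test(k, n) == pytest.approx(
                    binomial_two_sided_oracle(k, n), rel=1e-12), (k, n)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sg.subgroup_preference_test(5, 3)


@pytest.fixture(scope="module")
def planted_screen_data():
    """n=5,000 cohort with ~10% events and three planted GxE variants."""
    spec = sg.SimulationSpec(
        n_samples=5000, n_variants=120, seed=42, maf_range=(0.15, 0.45),
        ld_block_size=10, ld_rho=0.4, baseline_hazard_rate=0.008,
        variant_spacing_bp=60_000,
        causal_effects=[
            (20, 0.0, math.log(2.0)),          # pure interaction
            (60, 0.25, math.log(1.9)),         # main + interaction
            (100, -math.log(1.3), math.log(1.7)),  # crossover
        ])
    genos = sg.simulate_genotypes(spec)
    cohort = sg.simulate_cohort(spec, genos)
    return spec, genos, cohort


class TestInteractionFit:
    def test_planted_interaction_recovered_roughly(self, planted_screen_data):
        _, genos, cohort = planted_screen_data
        res = sg.test_interaction("snp20", "fos", "dementia", 1, cohort, genos)
        assert res.converged
        assert res.p_int < 1e-3
        assert res.beta_int == pytest.approx(math.log(2.0), abs=3 * res.se)

    def test_null_interaction_centered(self):
        rng = np.random.default_rng(0)
        betas = []
        for k in range(30):
            spec = sg.SimulationSpec(n_samples=1500, n_variants=1, seed=500 + k,
                                     maf_range=(0.3, 0.3),
                                     baseline_hazard_rate=0.01)
            genos = sg.simulate_genotypes(spec)
            cohort = sg.simulate_cohort(spec, genos)
            betas.append(sg.test_interaction("snp0", "fos", "dementia", 1,
                                             cohort, genos).beta_int)
        assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas)) + 0.05

    def test_continuous_exposure_standardized(self, planted_screen_data):
        _, genos, cohort = planted_screen_data
        res = sg.test_interaction("snp20", "omega3", "dementia", 1, cohort, genos)
        assert res.converged
        # rescaling the raw exposure must not change the result
        scaled = cohort.assign(omega3=cohort["omega3"] * 7.0 + 3.0)
        res2 = sg.test_interaction("snp20", "omega3", "dementia", 1, scaled, genos)
        assert res2.beta_int == pytest.approx(res.beta_int, rel=1e-6)


class TestSubgroupHRs:
    def test_crossover_directions_and_exposure_strata(self):
        """Planted crossover (exposure HR 0.77 in non-carriers, 2.2 in
        homozygous carriers): estimated HR_exposure straddles 1 across
        genotype groups and the SNP is harmful only under exposure."""
        spec = sg.SimulationSpec(
            n_samples=20_000, n_variants=1, seed=55, maf_range=(0.3, 0.3),
            baseline_hazard_rate=0.008, exposure_log_hr=math.log(0.77),
            causal_effects=[(0, 0.0, math.log(1.3 / 0.77))])
        genos = sg.simulate_genotypes(spec)
        cohort = sg.simulate_cohort(spec, genos)
        by_g, by_e = sg.subgroup_hrs("snp0", "fos", "dementia", cohort, genos)
        assert by_g["0"].wald.hr < 1.0 < by_g["2"].wald.hr
        assert by_e["exposed"].wald.hr > by_e["unexposed"].wald.hr
        assert by_e["exposed"].n == int((cohort["fos"] == 1).sum())

    def test_sparse_stratum_flagged_not_estimated(self):
        spec = sg.SimulationSpec(n_samples=600, n_variants=1, seed=77,
                                 maf_range=(0.04, 0.04),
                                 baseline_hazard_rate=0.004)
        genos = sg.simulate_genotypes(spec)
        cohort = sg.simulate_cohort(spec, genos)
        by_g, _ = sg.subgroup_hrs("snp0", "fos", "dementia", cohort, genos)
        assert by_g["2"].excluded
        assert by_g["2"].wald is None
        assert "events" in by_g["2"].reason or by_g["2"].reason == "no samples"

    def test_continuous_exposure_rejected(self, planted_screen_data):
        _, genos, cohort = planted_screen_data
        with pytest.raises(ValueError, match="binary"):
            sg.subgroup_hrs("snp20", "omega3", "dementia", cohort, genos)


class TestApoePositiveControl:
    def test_planted_e4_interaction_detected_and_exclusions_counted(self):
        from survgxe.cohort_prep import apoe_e4_dosage_column

        spec = sg.SimulationSpec(n_samples=20_000, n_variants=1, seed=88,
                                 baseline_hazard_rate=0.008,
                                 apoe_log_hr_interaction=math.log(1.6))
        genos = sg.simulate_genotypes(spec)
        cohort = sg.simulate_cohort(spec, genos)
        cohort["apoe_e4_dosage"] = apoe_e4_dosage_column(cohort)
        res = sg.apoe_positive_control(cohort, "fos", "dementia")
        assert res.p_int < 0.05
        assert res.beta_int > 0
        assert res.n == int(cohort["apoe_e4_dosage"].notna().sum())
        assert res.n < len(cohort)  # ambiguous diplotypes were excluded

    def test_missing_dosage_column_raises(self, planted_screen_data):
        _, _, cohort = planted_screen_data
        with pytest.raises(KeyError):
            sg.apoe_positive_control(cohort.drop(columns=["apoe_e4_true"]),
                                     "fos", "dementia")


class TestCompareModels:
    def test_identical_tables_give_unit_correlation(self):
        t = pd.DataFrame({"variant_id": ["a", "b", "c", "d"],
                          "beta_int": [0.1, -0.2, 0.05, 0.3],
                          "p_int": [0.01, 0.2, 0.5, 0.001]})
        out = sg.compare_models({1: t, 2: t.copy()})
        assert out["r_beta"].iloc[0] == pytest.approx(1.0)
        assert out["r_neglog10p"].iloc[0] == pytest.approx(1.0)

    def test_noise_covariates_leave_estimates_stable(self, planted_screen_data):
        """Model 2 adds covariates that carry no hazard signal in the
        generator, so interaction estimates correlate >0.95 with model 1."""
        _, genos, cohort = planted_screen_data
        ids = [f"snp{j}" for j in (0, 10, 20, 30, 40, 60, 80, 100, 110)]
        tables = {}
        for m in (1, 2):
            rows = [sg.test_interaction(v, "fos", "dementia", m, cohort, genos)
                    for v in ids]
            tables[m] = pd.DataFrame([{"variant_id": r.variant_id,
                                       "beta_int": r.beta_int,
                                       "p_int": r.p_int} for r in rows])
        out = sg.compare_models(tables)
        assert out["r_beta"].iloc[0] > 0.95
        assert out["r_neglog10p"].iloc[0] > 0.95

    def test_too_few_shared_variants(self):
        t1 = pd.DataFrame({"variant_id": ["a", "b", "c"],
                           "beta_int": [0.1, 0.2, 0.3], "p_int": [0.1] * 3})
        t2 = t1.iloc[:2]
        with pytest.raises(ValueError, match="shared"):
            sg.compare_models({1: t1, 2: t2})


class TestReplication:
    def test_same_exposure_self_replicates_and_sign_rule(self, planted_screen_data):
        _, genos, cohort = planted_screen_data
        locus = sg.Locus(chrom="1", start=1, end=2, index_variant="snp20",
                         members=["snp20"], min_p=1e-8,
                         member_pos={"snp20": 1_200_001})
        primary = sg.test_interaction("snp20", "fos", "dementia", 1, cohort, genos)
        prim_df = pd.DataFrame([{"variant_id": "snp20",
                                 "beta_int": primary.beta_int,
                                 "p_int": primary.p_int}])
        rep = sg.replicate_screen([locus], prim_df, "fos", cohort, genos)
        assert bool(rep["replicated"].iloc[0])
        # a sign-discordant primary coefficient blocks replication
        flipped = prim_df.assign(beta_int=-prim_df["beta_int"])
        rep2 = sg.replicate_screen([locus], flipped, "fos", cohort, genos)
        assert not bool(rep2["replicated"].iloc[0])

    def test_correlated_alternative_exposure_replicates_planted_locus(
            self, planted_screen_data):
        _, genos, cohort = planted_screen_data
        locus = sg.Locus(chrom="1", start=1, end=2, index_variant="snp60",
                         members=["snp60"], min_p=1e-8,
                         member_pos={"snp60": 3_600_001})
        primary = sg.test_interaction("snp60", "fos", "dementia", 1, cohort, genos)
        prim_df = pd.DataFrame([{"variant_id": "snp60",
                                 "beta_int": primary.beta_int,
                                 "p_int": primary.p_int}])
        rep = sg.replicate_screen([locus], prim_df, "fos_24h", cohort, genos)
        assert bool(rep["replicated"].iloc[0])


class TestRunScreen:
    def test_planted_loci_recovered_end_to_end(self, planted_screen_data):
        _, genos, cohort = planted_screen_data
        report = sg.run_screen(cohort, genos, models=(1,))
        assert report.n_candidate_loci_total >= 1
        assert report.bonferroni_p == pytest.approx(
            0.05 / report.n_candidate_loci_total)
        sig = report.interactions.loc[report.interactions["significant"]]
        planted = {"snp20", "snp60", "snp100"}
        assert len(planted & set(sig["variant_id"])) >= 2
        assert not report.loci_table.empty
        for out in report.preference.values():
            assert 0 <= out["k_user_only"] <= out["n_single_subgroup"]

    def test_rerun_is_byte_identical(self, planted_screen_data, tmp_path):
        _, genos, cohort = planted_screen_data
        genes = pd.DataFrame({
            "chrom": ["1"], "start": [1_000_000], "end": [1_500_000],
            "strand": ["+"], "symbol": ["GENE1"], "biotype": ["protein_coding"]})
        dirs = []
        for k in (0, 1):
            d = tmp_path / f"run{k}"
            sg.run_screen(cohort, genos, models=(1, 2),
                          alt_exposures=("fos_24h",), gene_table=genes,
                          known_loci=[("1", 1, 2_000_000)], seed=7, out_dir=d)
            dirs.append(d)
        files0 = sorted(p.name for p in dirs[0].iterdir())
        assert files0 == sorted(p.name for p in dirs[1].iterdir())
        assert "manifest.json" in files0 and "interactions.tsv" in files0
        for name in files0:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_null_screen_rarely_significant(self):
        hits = 0
        for k in range(3):
            spec = sg.SimulationSpec(n_samples=2500, n_variants=80, seed=900 + k,
                                     baseline_hazard_rate=0.008,
                                     variant_spacing_bp=60_000)
            genos = sg.simulate_genotypes(spec)
            cohort = sg.simulate_cohort(spec, genos)
            report = sg.run_screen(cohort, genos, models=(1,))
            hits += len(report.loci_table)
        assert hits <= 2
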