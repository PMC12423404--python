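"""Two-step gene-environment interaction screen.

Step one discovers candidate variants from the overall and
exposure-stratified GWAS at a lenient threshold (p < 1e-5, MAF > 0.01);
candidates are collapsed into independent loci by clumping with +/-250-kb
extension, and the locus count sets the Bonferroni-corrected interaction
threshold (0.05 / n_loci). Step two fits Cox models with a
SNP-by-exposure product term (model 1: age, sex, PC1-10; models 2-4 add
lifestyle, diet, and medical-history covariates), profiles subgroup hazard
ratios within genotype and exposure strata (groups with five or fewer
incident events are flagged, not estimated), runs the APOE e4 positive
control, assesses replication with alternative exposures, and compares
effect estimates across models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .cox_engine import NullCoxFit, WaldResult, fit_cox, model_terms, wald_test
from .loci import Locus, clump, extend_loci, nearest_gene, overlap_known
from .survival_gwas import run_gwas, variant_qc

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig", "InteractionResult", "SubgroupHR", "ScreenReport",
    "select_candidates", "bonferroni_threshold", "test_interaction",
    "subgroup_hrs", "apoe_positive_control", "replicate_screen",
    "compare_models", "subgroup_preference_test", "run_screen",
]


@dataclass
class ScreenConfig:
    """Thresholds and windows of the two-step screen."""

    candidate_p: float = 1e-5
    candidate_maf: float = 0.01
    gwas_significance: float = 5e-8
    bonferroni_alpha: float = 0.05
    clump_r2: float = 0.1
    window_bp: int = 250_000
    pad_bp: int = 250_000
    spa_switch_z: float = 2.0
    replication_alpha: float = 0.05
    min_subgroup_events: int = 5  # subgroups with <= this many events are excluded

    def __post_init__(self) -> None:
        for name in ("candidate_p", "candidate_maf", "gwas_significance",
                     "bonferroni_alpha", "replication_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1); got {v}")
        for name in ("window_bp", "pad_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SubgroupHR:
    """Exposure (or genotype) effect within one stratum, or an exclusion flag."""

    group: str
    n: int
    n_events: int
    wald: WaldResult | None
    excluded: bool
    reason: str = ""


@dataclass
class InteractionResult:
    variant_id: str
    outcome: str
    exposure: str
    model_id: int
    beta_int: float
    se: float
    p_int: float
    n: int
    n_events: int
    converged: bool
    significant: bool | None = None
    discovery_source: str = ""
    hr_exposure_by_genotype: dict[str, SubgroupHR] | None = None
    hr_dosage_by_exposure: dict[str, SubgroupHR] | None = None


def select_candidates(
    overall: pd.DataFrame,
    users: pd.DataFrame,
    nonusers: pd.DataFrame,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Union of variants reaching the suggestive threshold in any of the
    three GWAS, restricted to common variants (MAF > ``candidate_maf``);
    each candidate is tagged with every discovery source that reached the
    threshold and its minimum p across sources."""
    cfg = cfg or ScreenConfig()
    tables = {"overall": overall, "users": users, "nonusers": nonusers}
    maf = np.minimum(overall["af"].to_numpy(float), 1.0 - overall["af"].to_numpy(float))
    base = overall[["chrom", "pos", "id", "ref", "alt"]].copy()
    base["maf"] = maf
    hits: dict[str, set[str]] = {}
    pmin = pd.Series(np.inf, index=overall["id"])
    for src, tab in tables.items():
        sub = tab.loc[tab["p_spa"] < cfg.candidate_p, ["id", "p_spa"]]
        for vid, p in zip(sub["id"], sub["p_spa"]):
            hits.setdefault(vid, set()).add(src)
            if p < pmin.get(vid, np.inf):
                pmin[vid] = p
    sel = base.loc[base["id"].isin(hits) & (base["maf"] > cfg.candidate_maf)].copy()
    sel["sources"] = [",".join(sorted(hits[v])) for v in sel["id"]]
    sel["p_min"] = [float(pmin[v]) for v in sel["id"]]
    if sel.empty:
        logger.warning("no candidate variants reached p < %.3g", cfg.candidate_p)
    return sel.reset_index(drop=True)


def bonferroni_threshold(n_loci: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_loci over independent candidate loci."""
    if n_loci < 1:
        raise ValueError("n_loci must be at least 1")
    return alpha / n_loci


def _prepare_interaction_frame(
    cohort: pd.DataFrame, dosage: np.ndarray, exposure: str
) -> tuple[pd.DataFrame, str, str]:
    df = cohort.copy()
    df["_dosage"] = np.asarray(dosage, dtype=float)
    exp_vals = df[exposure].to_numpy(dtype=float)
    if len(np.unique(exp_vals[~np.isnan(exp_vals)])) > 2:
        sd = np.nanstd(exp_vals)
        df["_exp"] = (exp_vals - np.nanmean(exp_vals)) / (sd if sd > 0 else 1.0)
    else:
        df["_exp"] = exp_vals
    return df, "_exp", "_dosage"


def _interaction_fit(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    exposure: str,
    outcome: str,
    model_id: int,
    variant_id: str = "",
) -> InteractionResult:
    df, e, d = _prepare_interaction_frame(cohort, dosage, exposure)
    terms = model_terms(model_id) + [e, d, f"{d}:{e}"]
    try:
        fit = fit_cox(df, terms, outcome=outcome)
    except (ValueError, np.linalg.LinAlgError) as err:
        logger.warning("interaction fit failed for %s (%s): %s", variant_id, exposure, err)
        ev = outcome if outcome in df.columns else f"event_{outcome}"
        return InteractionResult(
            variant_id=variant_id, outcome=outcome, exposure=exposure,
            model_id=model_id, beta_int=np.nan, se=np.nan, p_int=np.nan,
            n=len(df), n_events=int(df[ev].sum()), converged=False)
    w = wald_test(fit, f"{d}:{e}")
    return InteractionResult(
        variant_id=variant_id, outcome=outcome, exposure=exposure,
        model_id=model_id, beta_int=w.beta, se=w.se, p_int=w.p,
        n=fit.n, n_events=fit.n_events, converged=fit.converged)


def test_interaction(
    variant_id: str,
    exposure: str,
    outcome: str,
    model_id: int,
    cohort: pd.DataFrame,
    genos: GenotypeMatrix,
) -> InteractionResult:
    """Fit a Cox model with the model's covariates plus exposure, SNP dosage
    and their product; the interaction p is the Wald p on the product term.
    Continuous exposures are standardized before forming the product."""
    j = genos.variant_index()[variant_id]
    dosage = genos.mean_imputed()[:, j]
    return _interaction_fit(cohort, dosage, exposure, outcome, model_id,
                            variant_id=variant_id)


def subgroup_hrs(
    variant_id: str,
    exposure: str,
    outcome: str,
    cohort: pd.DataFrame,
    genos: GenotypeMatrix,
    min_events: int = 5,
) -> tuple[dict[str, SubgroupHR], dict[str, SubgroupHR]]:
    """Exposure HR within each hard-called genotype group (0/1/2) and
    dosage HR within each exposure group, each adjusted for age, sex and
    PC1-10; strata with ``min_events`` or fewer incident events (or no
    samples) are flagged excluded rather than estimated."""
    j = genos.variant_index()[variant_id]
    hard = genos.hard_calls()[:, j]
    dosage = genos.mean_imputed()[:, j]
    ev_col = outcome if outcome in cohort.columns else f"event_{outcome}"
    base_terms = model_terms(1)

    def _fit_stratum(mask: np.ndarray, extra_col: str, extra_vals: np.ndarray,
                     group: str) -> SubgroupHR:
        n = int(mask.sum())
        n_ev = int(cohort.loc[mask, ev_col].sum())
        if n == 0:
            return SubgroupHR(group, 0, 0, None, True, "no samples")
        if n_ev <= min_events:
            return SubgroupHR(group, n, n_ev, None, True,
                              f"<= {min_events} incident events")
        df = cohort.loc[mask].reset_index(drop=True).copy()
        df["_term"] = extra_vals[mask]
        try:
            fit = fit_cox(df, base_terms + ["_term"], outcome=outcome)
            return SubgroupHR(group, n, n_ev, wald_test(fit, "_term"), False)
        except (ValueError, np.linalg.LinAlgError) as err:
            return SubgroupHR(group, n, n_ev, None, True, f"fit failed: {err}")

    exp_vals = cohort[exposure].to_numpy(dtype=float)
    by_genotype: dict[str, SubgroupHR] = {}
    for g in (0.0, 1.0, 2.0):
        mask = hard == g
        by_genotype[str(int(g))] = _fit_stratum(mask, exposure, exp_vals, str(int(g)))
    uniq = np.unique(exp_vals[~np.isnan(exp_vals)])
    if len(uniq) > 2:
        raise ValueError("exposure-stratified HRs require a binary exposure")
    by_exposure: dict[str, SubgroupHR] = {}
    for e, label in ((1.0, "exposed"), (0.0, "unexposed")):
        mask = exp_vals == e
        by_exposure[label] = _fit_stratum(mask, "_dosage", dosage, label)
    return by_genotype, by_exposure


def apoe_positive_control(
    cohort: pd.DataFrame,
    exposure: str = "fos",
    outcome: str = "dementia",
    model_id: int = 1,
    dosage_col: str = "apoe_e4_dosage",
) -> InteractionResult:
    """Interaction test with APOE e4 dosage (0/1/2) in place of a SNP
    dosage; samples with excluded (ambiguous or missing) e4 dosage are
    dropped from the fit."""
    if dosage_col not in cohort.columns:
        raise KeyError(f"cohort lacks {dosage_col!r}; derive it with cohort_prep first")
    keep = cohort[dosage_col].notna().to_numpy()
    sub = cohort.loc[keep].reset_index(drop=True)
    res = _interaction_fit(sub, sub[dosage_col].to_numpy(float), exposure,
                           outcome, model_id, variant_id="APOE_e4")
    return res


def replicate_screen(
    primary_loci: list[Locus],
    primary_results: pd.DataFrame,
    alt_exposure: str,
    cohort: pd.DataFrame,
    genos: GenotypeMatrix,
    outcome: str = "dementia",
    model_id: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus replication against an alternative exposure.

    A locus replicates iff at least one member SNP attains interaction
    p < ``alpha`` with the alternative exposure with an interaction
    coefficient of the same sign as its primary-analysis coefficient.
    Both components (best alt p, sign concordance) are reported so other
    rules can be recomputed.
    """
    beta_by_id = dict(zip(primary_results["variant_id"], primary_results["beta_int"]))
    rows = []
    for k, locus in enumerate(primary_loci):
        best_p, best_id, best_concordant = np.inf, "", False
        replicated = False
        for vid in locus.members:
            if vid not in beta_by_id:
                continue
            res = test_interaction(vid, alt_exposure, outcome, model_id, cohort, genos)
            if not np.isfinite(res.p_int):
                continue
            concordant = np.sign(res.beta_int) == np.sign(beta_by_id[vid])
            if res.p_int < best_p:
                best_p, best_id, best_concordant = res.p_int, vid, concordant
            if res.p_int < alpha and concordant:
                replicated = True
        rows.append({
            "locus": k, "index_variant": locus.index_variant,
            "alt_exposure": alt_exposure, "replicated": replicated,
            "best_alt_p": best_p if np.isfinite(best_p) else np.nan,
            "best_alt_variant": best_id, "best_sign_concordant": best_concordant,
        })
    return pd.DataFrame(rows)


def compare_models(results_by_model: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlations of interaction beta and -log10 p
    across adjustment models, on the shared variant set."""
    models = sorted(results_by_model)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    shared: set[str] | None = None
    for m in models:
        ids = set(results_by_model[m]["variant_id"])
        shared = ids if shared is None else shared & ids
    shared = sorted(shared or set())
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared variants across models")
    aligned = {}
    for m in models:
        t = results_by_model[m].set_index("variant_id").loc[shared]
        aligned[m] = (t["beta_int"].to_numpy(float),
                      -np.log10(t["p_int"].to_numpy(float)))
    rows = []
    for i, ma in enumerate(models):
        for mb in models[i + 1:]:
            rb, pb = stats.pearsonr(aligned[ma][0], aligned[mb][0])
            rp, pp = stats.pearsonr(aligned[ma][1], aligned[mb][1])
            rows.append({"model_a": ma, "model_b": mb,
                         "r_beta": float(rb), "p_beta": float(pb),
                         "r_neglog10p": float(rp), "p_neglog10p": float(pp),
                         "n_variants": len(shared)})
    return pd.DataFrame(rows)


def subgroup_preference_test(k_user_only: int, n_single_subgroup: int) -> float:
    """Two-sided exact binomial test of k in n against 0.5: the probability
    that a preference this extreme arises when loci are equally likely to be
    discovered in either exposure subgroup."""
    if not (0 <= k_user_only <= n_single_subgroup):
        raise ValueError("need 0 <= k <= n")
    if n_single_subgroup == 0:
        return 1.0
    return float(stats.binomtest(k_user_only, n_single_subgroup, 0.5).pvalue)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ScreenReport:
    """Bundle of all screen outputs for one run."""

    config: ScreenConfig
    seed: int
    n_candidate_loci: dict[str, int]
    n_candidate_loci_total: int
    bonferroni_p: float
    interactions: pd.DataFrame
    loci_table: pd.DataFrame
    loci: dict[str, list[Locus]]
    model_comparison: pd.DataFrame | None
    replication: pd.DataFrame | None
    preference: dict[str, dict]
    qc: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "package": "survgxe",
            "version": _version(),
            "seed": self.seed,
            "config": asdict(self.config),
            "n_candidate_loci": self.n_candidate_loci,
            "n_candidate_loci_total": self.n_candidate_loci_total,
            "bonferroni_p": self.bonferroni_p,
            "qc": self.qc,
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, tab in (("interactions", self.interactions),
                          ("loci", self.loci_table)):
            p = out_dir / f"{name}.tsv"
            tab.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths[name] = p
        if self.model_comparison is not None:
            p = out_dir / "models_compare.tsv"
            self.model_comparison.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths["models_compare"] = p
        if self.replication is not None:
            p = out_dir / "replication.tsv"
            self.replication.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths["replication"] = p
        p = out_dir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = p
        return paths


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("survgxe")
    except Exception:  # pragma: no cover
        return "unknown"


def _fmt_hr(sub: SubgroupHR) -> str:
    if sub.excluded or sub.wald is None:
        return "-"
    return f"{sub.wald.hr:.2f} ({sub.wald.ci95[0]:.2f}, {sub.wald.ci95[1]:.2f})"


def run_screen(
    cohort: pd.DataFrame,
    genos: GenotypeMatrix,
    cfg: ScreenConfig | None = None,
    exposure: str = "fos",
    outcomes: tuple[str, ...] = ("dementia",),
    alt_exposures: tuple[str, ...] = (),
    models: tuple[int, ...] = (1,),
    gene_table: pd.DataFrame | None = None,
    known_loci: list[tuple[str, int, int]] | None = None,
    apply_qc: bool = True,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ScreenReport:
    """Run the full two-step screen and return (optionally write) the report.

    Stages: variant QC; overall and exposure-stratified GWAS per outcome;
    candidate selection; clumping with extension into independent loci;
    a single pooled Bonferroni denominator across outcomes; model-1
    interaction tests per candidate with significance flags; subgroup HR
    profiles and nearest-gene annotation for significant loci; optional
    models 2-4 comparison, alternative-exposure replication, and the
    subgroup-preference binomial test. Deterministic given inputs and seed.
    """
    import time as _time

    cfg = cfg or ScreenConfig()
    qc_info: dict = {}
    if apply_qc:
        t0 = _time.perf_counter()
        genos, qc_report = variant_qc(genos)
        qc_info = {
            "n_variants_in": qc_report.n_variants_in,
            "n_variants_out": qc_report.n_variants_out,
            "variant_removals": qc_report.variant_removals,
            "n_samples_out": qc_report.n_samples_out,
        }
        if qc_report.n_samples_out != qc_report.n_samples_in:
            keep = set(genos.sample_ids)
            cohort = cohort.loc[cohort["sample_id"].isin(keep)].reset_index(drop=True)
        logger.info("QC: %d -> %d variants (%.2fs)", qc_report.n_variants_in,
                    qc_report.n_variants_out, _time.perf_counter() - t0)

    per_outcome_loci: dict[str, list[Locus]] = {}
    per_outcome_cands: dict[str, pd.DataFrame] = {}
    gwas_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for outcome in outcomes:
        t0 = _time.perf_counter()
        overall = run_gwas(genos, cohort, outcome, spa_switch_z=cfg.spa_switch_z)
        users = run_gwas(genos, cohort, outcome, subgroup=(exposure, 1.0),
                         spa_switch_z=cfg.spa_switch_z)
        nonusers = run_gwas(genos, cohort, outcome, subgroup=(exposure, 0.0),
                            spa_switch_z=cfg.spa_switch_z)
        gwas_tables[(outcome, "overall")] = overall
        gwas_tables[(outcome, "users")] = users
        gwas_tables[(outcome, "nonusers")] = nonusers
        cands = select_candidates(overall, users, nonusers, cfg)
        per_outcome_cands[outcome] = cands
        if cands.empty:
            per_outcome_loci[outcome] = []
        else:
            ctab = cands.rename(columns={"p_min": "p"})[["chrom", "pos", "id", "p"]]
            clumps = clump(ctab, genos, p_threshold=cfg.candidate_p,
                           r2_threshold=cfg.clump_r2, window_bp=cfg.window_bp,
                           p_col="p", source=outcome)
            per_outcome_loci[outcome] = extend_loci(clumps, pad_bp=cfg.pad_bp)
        logger.info("GWAS + loci for %s: %d candidates, %d loci (%.2fs)",
                    outcome, len(cands), len(per_outcome_loci[outcome]),
                    _time.perf_counter() - t0)

    n_loci = {o: len(l) for o, l in per_outcome_loci.items()}
    total_loci = sum(n_loci.values())
    bonf = bonferroni_threshold(max(total_loci, 1), cfg.bonferroni_alpha)

    inter_rows = []
    loci_rows = []
    repl_frames = []
    preference: dict[str, dict] = {}
    results_by_model: dict[int, list[pd.DataFrame]] = {m: [] for m in models}
    for outcome in outcomes:
        cands = per_outcome_cands[outcome]
        loci_list = per_outcome_loci[outcome]
        locus_of = {}
        for k, locus in enumerate(loci_list):
            for vid in locus.members:
                locus_of[vid] = k
        primary = []
        for _, row in cands.iterrows():
            res = test_interaction(row["id"], exposure, outcome, 1, cohort, genos)
            res.discovery_source = row["sources"]
            res.significant = bool(np.isfinite(res.p_int) and res.p_int < bonf)
            primary.append(res)
            inter_rows.append({
                "outcome": outcome, "variant_id": res.variant_id,
                "chrom": row["chrom"], "pos": row["pos"],
                "ref": row["ref"], "alt": row["alt"], "maf": row["maf"],
                "locus": locus_of.get(res.variant_id, -1),
                "discovery_source": res.discovery_source,
                "gwas_p_min": row["p_min"],
                "beta_int": res.beta_int, "se_int": res.se, "p_int": res.p_int,
                "significant": res.significant, "converged": res.converged,
            })
        primary_df = pd.DataFrame(
            [{"variant_id": r.variant_id, "beta_int": r.beta_int,
              "p_int": r.p_int} for r in primary]
        ) if primary else pd.DataFrame(columns=["variant_id", "beta_int", "p_int"])
        for m in models:
            if m == 1:
                results_by_model[m].append(pd.DataFrame(
                    [{"variant_id": r.variant_id, "beta_int": r.beta_int,
                      "p_int": r.p_int, "outcome": outcome} for r in primary],
                    columns=["variant_id", "beta_int", "p_int", "outcome"]))
            else:
                rows_m = []
                for _, row in cands.iterrows():
                    rm = test_interaction(row["id"], exposure, outcome, m, cohort, genos)
                    rows_m.append({"variant_id": rm.variant_id, "beta_int": rm.beta_int,
                                   "p_int": rm.p_int, "outcome": outcome})
                results_by_model[m].append(pd.DataFrame(
                    rows_m, columns=["variant_id", "beta_int", "p_int", "outcome"]))

        # significant loci: Table-1 style rows
        sig_ids = {r.variant_id for r in primary if r.significant}
        known_flags = overlap_known(loci_list, known_loci) if known_loci is not None else None
        sig_loci = []
        for k, locus in enumerate(loci_list):
            members_sig = [r for r in primary
                           if r.variant_id in locus.members and r.significant]
            if not members_sig:
                continue
            top = min(members_sig, key=lambda r: r.p_int)
            sig_loci.append(locus)
            gene, dist = ("", -1)
            if gene_table is not None:
                pos = locus.member_pos.get(top.variant_id, locus.start)
                gene, dist = nearest_gene(locus.chrom, pos, gene_table)
            by_g, by_e = subgroup_hrs(top.variant_id, exposure, outcome,
                                      cohort, genos,
                                      min_events=cfg.min_subgroup_events)
            vrow = cands.loc[cands["id"] == top.variant_id].iloc[0]
            loci_rows.append({
                "outcome": outcome, "chrom": locus.chrom, "locus": k,
                "start": locus.start, "end": locus.end,
                "top_snp": top.variant_id, "closest_gene": gene,
                "gene_distance_bp": dist,
                "ref": vrow["ref"], "alt": vrow["alt"],
                "p_interaction": top.p_int,
                "hr_exposure_g0": _fmt_hr(by_g["0"]),
                "hr_exposure_g1": _fmt_hr(by_g["1"]),
                "hr_exposure_g2": _fmt_hr(by_g["2"]),
                "hr_snp_exposed": _fmt_hr(by_e["exposed"]),
                "hr_snp_unexposed": _fmt_hr(by_e["unexposed"]),
                "known": bool(known_flags[k]) if known_flags is not None else "",
            })
        for alt in alt_exposures:
            if sig_loci:
                rep = replicate_screen(sig_loci, primary_df, alt, cohort, genos,
                                       outcome=outcome, alpha=cfg.replication_alpha)
                rep.insert(0, "outcome", outcome)
                repl_frames.append(rep)

        # subgroup-discovery preference among loci suggestive in exactly one stratum
        users_tab = gwas_tables[(outcome, "users")].set_index("id")
        nonusers_tab = gwas_tables[(outcome, "nonusers")].set_index("id")
        n_single = k_users = 0
        for locus in loci_list:
            in_users = any(users_tab.loc[v, "p_spa"] < cfg.candidate_p
                           for v in locus.members if v in users_tab.index)
            in_non = any(nonusers_tab.loc[v, "p_spa"] < cfg.candidate_p
                         for v in locus.members if v in nonusers_tab.index)
            if in_users != in_non:
                n_single += 1
                k_users += int(in_users)
        preference[outcome] = {
            "n_single_subgroup": n_single, "k_user_only": k_users,
            "p_binomial": subgroup_preference_test(k_users, n_single),
        }

    interactions = pd.DataFrame(inter_rows)
    loci_table = pd.DataFrame(loci_rows, columns=[
        "outcome", "chrom", "locus", "start", "end", "top_snp", "closest_gene",
        "gene_distance_bp", "ref", "alt", "p_interaction",
        "hr_exposure_g0", "hr_exposure_g1", "hr_exposure_g2",
        "hr_snp_exposed", "hr_snp_unexposed", "known"])
    comparison = None
    if len(models) > 1:
        merged = {m: pd.concat(results_by_model[m], ignore_index=True)
                  for m in models}
        ok = all(len(t.dropna(subset=["p_int"])) >= 3 for t in merged.values())
        if ok:
            try:
                comparison = compare_models(
                    {m: t.dropna(subset=["p_int"]) for m, t in merged.items()})
            except ValueError as err:
                logger.warning("model comparison skipped: %s", err)
    replication = pd.concat(repl_frames, ignore_index=True) if repl_frames else None
    report = ScreenReport(
        config=cfg, seed=seed, n_candidate_loci=n_loci,
        n_candidate_loci_total=total_loci, bonferroni_p=bonf,
        interactions=interactions, loci_table=loci_table, loci=per_outcome_loci,
        model_comparison=comparison, replication=replication,
        preference=preference, qc=qc_info)
    if out_dir is not None:
        report.write(out_dir)
    return report
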