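"""Time-to-event GWAS: QC, relatedness pruning, and SPA score tests.

The per-variant association statistic is a Cox score test built on a single
null-model fit: the genotype dosage is residualized on the null covariates
(plus intercept), the score is the inner product of the residualized dosage
with the null-model martingale residuals, and its variance is the exact
genotype-permutation variance, so z^2 is chi-square calibrated under
permutation by construction. Because martingale residuals are heavily
skewed when events are rare, normal tail probabilities are anti-conservative
far in the tail; beyond |z| > 2 the tail is therefore recomputed by a
saddlepoint approximation (Lugannani-Rice) of the score's null cumulant
generating function, treating residuals as fixed and the genotype at each
sample as an independent Hardy-Weinberg draw centered at its mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import GenotypeMatrix
from .cox_engine import NullCoxFit, fit_cox, model_terms

logger = logging.getLogger(__name__)

__all__ = [
    "QcThresholds", "QcReport", "ScoreTestResult",
    "variant_qc", "hwe_exact_test", "prune_relatives",
    "score_test", "run_gwas", "genomic_inflation",
]

#: kinship coefficient separating third-degree relatives from unrelated pairs
THIRD_DEGREE_KINSHIP = 0.0442


@dataclass
class QcThresholds:
    """Variant- and sample-level QC cutoffs.

    Defaults: drop variants with imputation info < 0.3, non-biallelic sites,
    MAF < 0.1%, call rate < 95%, or HWE exact p < 1e-8; then drop samples
    with call rate < 98%.
    """

    info_min: float = 0.3
    maf_min: float = 0.001
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-8
    sample_call_rate_min: float = 0.98


# fixed filter order so report attribution is deterministic
_VARIANT_FILTERS = ("info", "biallelic", "maf", "missingness", "hwe")


@dataclass
class QcReport:
    n_variants_in: int = 0
    n_variants_out: int = 0
    variant_removals: dict[str, int] = field(default_factory=dict)
    n_samples_in: int = 0
    n_samples_out: int = 0
    sample_removals: dict[str, int] = field(default_factory=dict)

    def check_totals(self) -> bool:
        return (
            self.n_variants_in - sum(self.variant_removals.values()) == self.n_variants_out
            and self.n_samples_in - sum(self.sample_removals.values()) == self.n_samples_out
        )


def variant_qc(
    genos: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply variant filters in fixed order (info, biallelic, MAF,
    missingness, HWE), then the per-sample call-rate filter.

    A variant failing several filters is attributed to the first failing
    one. HWE is tested on hard-called genotypes (dosages rounded half to
    even). Raises if nothing survives.
    """
    thr = thresholds or QcThresholds()
    report = QcReport(
        n_variants_in=genos.n_variants,
        n_samples_in=genos.n_samples,
        variant_removals={k: 0 for k in _VARIANT_FILTERS},
        sample_removals={"call_rate": 0},
    )
    af = genos.allele_freq()
    maf = np.minimum(af, 1.0 - af)
    call_rate = genos.call_rate()
    hard = genos.hard_calls()
    keep = np.ones(genos.n_variants, dtype=bool)
    for j in range(genos.n_variants):
        v = genos.variants[j]
        if v.info < thr.info_min:
            report.variant_removals["info"] += 1
        elif not v.is_biallelic:
            report.variant_removals["biallelic"] += 1
        elif not (maf[j] >= thr.maf_min):
            report.variant_removals["maf"] += 1
        elif call_rate[j] < thr.call_rate_min:
            report.variant_removals["missingness"] += 1
        else:
            col = hard[:, j]
            col = col[~np.isnan(col)]
            p_hwe = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                   int((col == 2).sum()))
            v.hwe_p = p_hwe
            if p_hwe < thr.hwe_p_min:
                report.variant_removals["hwe"] += 1
            else:
                v.maf = float(maf[j])
                v.call_rate = float(call_rate[j])
                continue
        keep[j] = False
    if not keep.any():
        raise ValueError("all variants removed by QC")
    out = genos.take_variants(np.flatnonzero(keep))
    sample_cr = out.sample_call_rate()
    keep_s = sample_cr >= thr.sample_call_rate_min
    report.sample_removals["call_rate"] = int((~keep_s).sum())
    if not keep_s.all():
        out = out.take_samples(np.flatnonzero(keep_s))
    report.n_variants_out = out.n_variants
    report.n_samples_out = out.n_samples
    return out, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose probability does not exceed the observed
    one. Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2          # rare-allele homozygotes
    homc = (2 * n - rare - hets) // 2  # common-allele homozygotes
    # log P(het=h | allele counts) up to the common normalizer
    logp = (hets * np.log(2.0) - gammaln(hets + 1)
            - gammaln(homr + 1) - gammaln(homc + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def prune_relatives(
    pairs: list[tuple[str, str, float]],
    samples: list[str],
    seed: int = 0,
    kinship_cutoff: float = THIRD_DEGREE_KINSHIP,
    max_pairs: int = 10,
) -> list[str]:
    """Remove one member of each related pair closer than third degree.

    Samples appearing in more than ``max_pairs`` qualifying pairs are
    removed first (excessive relatedness); the remaining qualifying pairs
    are then visited in deterministic sorted order and, when both members
    are still present, one is removed uniformly at random (seeded).
    Returns the kept sample ids in input order.
    """
    sample_set = set(samples)
    for a, b, k in pairs:
        if a not in sample_set or b not in sample_set:
            raise ValueError(f"pair ({a}, {b}) refers to unknown sample id")
        if k < 0:
            raise ValueError("kinship must be non-negative")
    close = [(a, b) for a, b, k in pairs if k > kinship_cutoff]
    counts: dict[str, int] = {}
    for a, b in close:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    removed = {s for s, c in counts.items() if c > max_pairs}
    rng = np.random.default_rng(seed)
    for a, b in sorted(close):
        if a in removed or b in removed:
            continue
        removed.add(a if rng.integers(2) == 0 else b)
    return [s for s in samples if s not in removed]


@dataclass
class ScoreTestResult:
    variant_id: str
    af: float
    n: int
    n_events: int
    score: float
    variance: float
    z: float
    p_normal: float
    p_spa: float
    method_used: str  # normal | spa | spa_failed_fallback | non_testable


# ---------------------------------------------------------------------------
# saddlepoint machinery


def _cgf(t: float, r: np.ndarray, probs: np.ndarray, offsets: np.ndarray):
    """CGF (and first two derivatives) of sum_i (G_i - mu) r_i with G_i iid
    3-point Hardy-Weinberg draws; residuals r fixed."""
    a = np.multiply.outer(r, offsets)  # (n, 3)
    ta = t * a
    m = ta.max(axis=1, keepdims=True)
    e = probs * np.exp(ta - m)
    s0 = e.sum(axis=1)
    s1 = (e * a).sum(axis=1)
    s2 = (e * a * a).sum(axis=1)
    K = float((m[:, 0] + np.log(s0)).sum())
    K1 = float((s1 / s0).sum())
    K2 = float((s2 / s0 - (s1 / s0) ** 2).sum())
    return K, K1, K2


def _saddlepoint_tail(s: float, r: np.ndarray, probs: np.ndarray,
                      offsets: np.ndarray, k2_0: float) -> float | None:
    """P(S >= s) for s > 0 (or P(S <= s) for s < 0) by Lugannani-Rice.

    Returns None when the saddlepoint equation has no root in range
    (score beyond the support of the null distribution).
    """
    if s == 0.0:
        return 0.5
    # bracket the root of K'(z) = s (K' is strictly increasing, bounded by
    # the support of the null distribution)
    from scipy.optimize import brentq

    hi = max(abs(s) / k2_0, 1e-8) * np.sign(s)
    lo = 0.0
    for _ in range(200):
        if (_cgf(hi, r, probs, offsets)[1] - s) * np.sign(s) >= 0:
            break
        lo = hi
        hi *= 2.0
        if abs(hi) > 1e9:
            return None  # score outside the attainable support
    else:
        return None
    if lo > hi:
        lo, hi = hi, lo
    try:
        z = brentq(lambda t: _cgf(t, r, probs, offsets)[1] - s, lo, hi,
                   xtol=1e-12, rtol=1e-12, maxiter=200)
    except (ValueError, RuntimeError):
        return None
    K, K1, K2 = _cgf(z, r, probs, offsets)
    arg = 2.0 * (z * s - K)
    if arg < 0 or K2 <= 0:
        return None
    w = np.sign(z) * np.sqrt(arg)
    v = z * np.sqrt(K2)
    if abs(w) < 1e-5 or abs(v) < 1e-12:
        # degenerate near the center: normal tail
        return float(stats.norm.sf(abs(s) / np.sqrt(k2_0)))
    if s > 0:
        p = stats.norm.sf(w) - stats.norm.pdf(w) * (1.0 / w - 1.0 / v)
    else:
        p = stats.norm.cdf(w) + stats.norm.pdf(w) * (1.0 / w - 1.0 / v)
    if not (0.0 < p < 1.0):
        # Barndorff-Nielsen form as a numerically safer fallback
        u = w + np.log(v / w) / w
        p = float(stats.norm.sf(u)) if s > 0 else float(stats.norm.cdf(u))
    if not (0.0 < p < 1.0):
        return None
    return float(p)


def score_test(
    dosage: np.ndarray,
    null: NullCoxFit,
    spa_switch_z: float = 2.0,
    variant_id: str = "",
) -> ScoreTestResult:
    """Cox score test of one dosage vector against a fitted null model.

    Missing dosages are mean-imputed; the dosage is residualized on the
    null covariates; S = sum g~_i r_i with r the martingale residuals;
    Var(S) is the exact permutation variance (sum g~^2) (sum r^2) / (n-1).
    When |z| exceeds ``spa_switch_z`` the tail probability is recomputed by
    saddlepoint approximation; root-finding failure falls back to the
    normal p with ``method_used='spa_failed_fallback'``.
    """
    g = np.asarray(dosage, dtype=float).copy()
    n = null.n
    if g.shape != (n,):
        raise ValueError("dosage length does not match null fit")
    if np.isnan(g).any():
        g[np.isnan(g)] = np.nanmean(g)
    af = float(np.mean(g) / 2.0)
    r = null.martingale_residuals
    g_res = null.residualize(g)
    ssg = float(g_res @ g_res)
    base = dict(variant_id=variant_id, af=af, n=n, n_events=null.n_events)
    if ssg <= 1e-12 * n:
        return ScoreTestResult(**base, score=0.0, variance=0.0, z=0.0,
                               p_normal=np.nan, p_spa=np.nan,
                               method_used="non_testable")
    S = float(g_res @ r)
    V = ssg * float(r @ r) / (n - 1)
    if V <= 0:
        return ScoreTestResult(**base, score=S, variance=V, z=0.0,
                               p_normal=1.0, p_spa=1.0, method_used="normal")
    z = S / np.sqrt(V)
    p_normal = float(2.0 * stats.norm.sf(abs(z)))
    method = "normal"
    p_spa = p_normal
    if abs(z) > spa_switch_z:
        p = _spa_two_sided(S, V, af, r)
        if p is None:
            method = "spa_failed_fallback"
        else:
            method = "spa"
            p_spa = p
    p_normal = max(p_normal, np.finfo(float).tiny)
    p_spa = max(p_spa, np.finfo(float).tiny)
    return ScoreTestResult(**base, score=S, variance=V, z=float(z),
                           p_normal=p_normal, p_spa=p_spa, method_used=method)


def _spa_two_sided(S: float, V: float, af: float, r: np.ndarray) -> float | None:
    p_allele = min(max(af, 1e-6), 1 - 1e-6)
    q = 1.0 - p_allele
    probs = np.array([q * q, 2 * p_allele * q, p_allele * p_allele])
    mu = 2.0 * p_allele
    offsets = np.array([0.0 - mu, 1.0 - mu, 2.0 - mu])
    k2_0 = 2.0 * p_allele * q * float(r @ r)
    if k2_0 <= 0:
        return None
    # scale the observed score so its variance matches the CGF's variance
    s_adj = abs(S) * np.sqrt(k2_0 / V)
    upper = _saddlepoint_tail(s_adj, r, probs, offsets, k2_0)
    lower = _saddlepoint_tail(-s_adj, r, probs, offsets, k2_0)
    if upper is None or lower is None:
        return None
    return float(min(1.0, upper + lower))


def run_gwas(
    genos: GenotypeMatrix,
    cohort: pd.DataFrame,
    outcome: str = "dementia",
    covariates: str | list[str] = "model1",
    subgroup: tuple[str, float] | None = None,
    spa_switch_z: float = 2.0,
    out: str | None = None,
) -> pd.DataFrame:
    """Scan every variant for association with a time-to-event outcome.

    Fits one null Cox model (default model-1 covariates: age, sex, PC1-10)
    on the full cohort or, when ``subgroup=(column, value)`` is given, on
    that exposure stratum only, then applies the SPA score test to every
    variant. Residualization is vectorized across variants. Returns (and
    optionally writes) a summary-statistics table.
    """
    terms = model_terms(covariates) if isinstance(covariates, str) else list(covariates)
    table = cohort
    geno = genos
    if subgroup is not None:
        col, val = subgroup
        mask = (cohort[col] == val).to_numpy()
        table = cohort.loc[mask].reset_index(drop=True)
        geno = genos.take_samples(np.flatnonzero(mask))
    ev_col = outcome if outcome in table.columns else f"event_{outcome}"
    if table[ev_col].sum() < 1:
        raise ValueError(f"no events in {'subgroup ' + str(subgroup) if subgroup else 'cohort'}")
    null = fit_cox(table, terms, outcome=outcome)
    r = null.martingale_residuals
    rss = float(r @ r)
    n = null.n
    G = geno.mean_imputed()
    G_res = null.residualize(G)
    S = G_res.T @ r
    ssg = np.einsum("ij,ij->j", G_res, G_res)
    V = ssg * rss / (n - 1)
    af = G.mean(axis=0) / 2.0
    testable = ssg > 1e-12 * n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(testable & (V > 0), S / np.sqrt(V), 0.0)
    p_normal = 2.0 * stats.norm.sf(np.abs(z))
    p_spa = p_normal.copy()
    method = np.where(testable, "normal", "non_testable").astype(object)
    tiny = np.finfo(float).tiny
    for j in np.flatnonzero(testable & (np.abs(z) > spa_switch_z)):
        p = _spa_two_sided(float(S[j]), float(V[j]), float(af[j]), r)
        if p is None:
            method[j] = "spa_failed_fallback"
        else:
            method[j] = "spa"
            p_spa[j] = p
    p_normal = np.maximum(p_normal, tiny)
    p_spa = np.maximum(p_spa, tiny)
    p_normal[~testable] = np.nan
    p_spa[~testable] = np.nan
    res = pd.DataFrame({
        "chrom": [v.chrom for v in geno.variants],
        "pos": [v.pos for v in geno.variants],
        "id": [v.id for v in geno.variants],
        "ref": [v.ref for v in geno.variants],
        "alt": [v.alt for v in geno.variants],
        "af": af,
        "n": n,
        "n_events": null.n_events,
        "score": S,
        "z": z,
        "p_normal": p_normal,
        "p_spa": p_spa,
        "method": method,
    })
    if out is not None:
        from . import dataio

        dataio.write_summary_stats(res, out)
    return res


def genomic_inflation(results) -> float:
    """Genomic inflation factor: median observed chi-square (z^2) over the
    null chi-square median (~0.4549)."""
    if isinstance(results, pd.DataFrame):
        z = results["z"].to_numpy(dtype=float)
    else:
        z = np.asarray(results, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 100:
        raise ValueError("genomic inflation requires at least 100 test statistics")
    return float(np.median(z**2) / stats.chi2.ppf(0.5, 1))
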