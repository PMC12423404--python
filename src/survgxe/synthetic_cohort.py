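"""Synthetic biobank-style cohort generator with planted G and GxE effects.

Emulates the statistical structure the downstream screen assumes: genotypes
in Hardy-Weinberg proportions with tunable block LD (Gaussian-copula
thresholding with first-order autoregressive latent correlation), a cohort
with truncated-normal entry ages (default mean 56.81, SD 8.01, range 40-69),
~31.7% binary supplement exposure, standard-normal synthetic genetic PCs,
lifestyle/diet/medical covariates for the model-2-4 adjustments, APOE-defining
SNP genotypes, and censored event times drawn from a constant-baseline
proportional-hazards model whose linear predictor carries user-specified
genotype main effects and genotype-by-exposure interaction effects.

All randomness derives from one integer seed; identical specs produce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtr

from .containers import GenotypeMatrix, VariantRecord

__all__ = ["SimulationSpec", "simulate_genotypes", "simulate_cohort", "write_fixture"]

# APOE epsilon haplotype frequencies used for the synthetic rs429358/rs7412
# genotypes (European-ancestry ballpark; epsilon-1 is vanishingly rare and
# omitted from the generator, though the dosage decoder handles it).
_APOE_HAP_FREQS = {"e2": 0.08, "e3": 0.77, "e4": 0.15}
# haplotype -> (rs429358 allele, rs7412 allele)
_APOE_HAP_ALLELES = {"e2": ("T", "T"), "e3": ("T", "C"), "e4": ("C", "C")}

OILY_FISH_LEVELS = [
    "never",
    "less than once a week",
    "once a week",
    "2-4 times a week",
    "5-6 times a week",
    "once or more daily",
]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort; defaults mirror the target cohort
    (entry age 56.81 +/- 8.01 within 40-69 years, 31.7% exposed, low event
    rate with administrative censoring at 13.8 years of follow-up)."""

    n_samples: int = 2000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.0
    exposure_prevalence: float = 0.317
    age_mean: float = 56.81
    age_sd: float = 8.01
    entry_age_range: tuple[float, float] = (40.0, 69.0)
    baseline_hazard_rate: float = 0.0015  # events per person-year
    admin_censor_years: float = 13.8
    causal_effects: list[tuple[int, float, float]] = field(default_factory=list)
    exposure_log_hr: float = math.log(0.92)
    covariate_log_hrs: dict[str, float] = field(
        default_factory=lambda: {"age": 0.075, "sex": 0.30}
    )
    missing_genotype_rate: float = 0.0
    seed: int = 0
    variant_spacing_bp: int = 5000
    chrom: str = "1"
    exposure_confounded: bool = False
    apoe_log_hr_main: float = 0.0
    apoe_log_hr_interaction: float = 0.0
    covariate_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5]; got {self.maf_range}")
        if not (0.0 < self.exposure_prevalence < 1.0):
            raise ValueError("exposure_prevalence must be in (0,1)")
        for name in ("n_samples", "n_variants", "ld_block_size", "variant_spacing_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0,1)")
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ValueError("missing_genotype_rate must be in [0,1)")
        for j, _, _ in self.causal_effects:
            if not (0 <= j < self.n_variants):
                raise ValueError(f"causal variant index {j} out of range")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stream generator derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw a samples-x-variants dosage matrix with HWE marginals and block LD.

    Allele frequencies are uniform over ``maf_range``. Within each block of
    ``ld_block_size`` variants, latent Gaussians follow an AR(1) process with
    correlation ``ld_rho`` and are thresholded at the HWE genotype-class
    quantiles, so marginal genotype frequencies are exactly Hardy-Weinberg
    while adjacent variants share LD. A trailing short block is allowed.
    Missing calls are planted completely at random.
    """
    rng = spec.rng(0)
    n, m = spec.n_samples, spec.n_variants
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    z = rng.standard_normal((n, m))
    if spec.ld_rho > 0:
        carry = math.sqrt(1.0 - spec.ld_rho**2)
        for j in range(1, m):
            if j % spec.ld_block_size == 0:
                continue  # new block: fresh latent
            z[:, j] = spec.ld_rho * z[:, j - 1] + carry * z[:, j]
    u = ndtr(z)
    q = 1.0 - mafs
    thr0 = q**2          # P(G=0)
    thr1 = q**2 + 2 * mafs * q
    dosages = (u >= thr0).astype(float) + (u >= thr1)
    if spec.missing_genotype_rate > 0:
        miss = spec.rng(3).random((n, m)) < spec.missing_genotype_rate
        dosages[miss] = np.nan
    variants = [
        VariantRecord(
            chrom=spec.chrom,
            pos=1 + j * spec.variant_spacing_bp,
            id=f"snp{j}",
            ref="A",
            alt="G",
            maf=float(mafs[j]),
            info=1.0,
        )
        for j in range(m)
    ]
    genos = GenotypeMatrix(dosages=dosages, variants=variants,
                           sample_ids=[f"S{i:06d}" for i in range(n)])
    cr = genos.call_rate()
    af = genos.allele_freq()
    for j, v in enumerate(genos.variants):
        v.call_rate = float(cr[j])
        v.maf = float(min(af[j], 1.0 - af[j]))
    return genos


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws whose post-truncation mean/SD match the target.

    The underlying location/scale are solved so that the truncated
    distribution itself has the requested moments (plain truncation of
    N(mean, sd) would bias the mean toward the interval midpoint).
    """
    from scipy.optimize import fsolve

    def moments(params):
        loc, log_scale = params
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    loc, log_scale = fsolve(moments, [mean, math.log(sd)], xtol=1e-10)
    scale = math.exp(log_scale)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def simulate_cohort(spec: SimulationSpec, genos: GenotypeMatrix) -> pd.DataFrame:
    """Generate covariates, exposures, and censored event times.

    The hazard is h(t) = r0 * exp(eta) with constant baseline rate r0 and

        eta = sum_c beta_c * x_c  +  beta_E * E
              + sum_j (beta_main_j * G_j + beta_int_j * G_j * E)
              + APOE main/interaction terms,

    with age centered at its mean so r0 stays interpretable as the typical
    event rate. Time-on-study is the survival timescale (entry age is a
    covariate, not a delayed-entry time). Event times are exponential given
    eta and administratively censored at ``admin_censor_years``. Events are
    split into Alzheimer's / vascular / other subtypes so the three outcome
    columns share one follow-up time.
    """
    if genos.n_samples != spec.n_samples:
        raise ValueError(
            f"genotype matrix has {genos.n_samples} samples but spec expects "
            f"{spec.n_samples}: misaligned inputs"
        )
    rng = spec.rng(1)
    n = spec.n_samples
    age = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.entry_age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 10))
    if spec.exposure_confounded:
        logit0 = math.log(spec.exposure_prevalence / (1 - spec.exposure_prevalence))
        p_exp = expit(logit0 + 0.03 * (age - spec.age_mean) + 0.25 * (sex - 0.5))
    else:
        p_exp = np.full(n, spec.exposure_prevalence)
    fos = (rng.random(n) < p_exp).astype(float)

    # alternative exposures, correlated with FOS for replication testing
    fos_24h = np.where(rng.random(n) < 0.9, fos, 1.0 - fos)
    oily_fish_level = rng.choice(len(OILY_FISH_LEVELS), size=n,
                                 p=[0.12, 0.28, 0.30, 0.24, 0.04, 0.02])
    oily_fish = (oily_fish_level >= 2).astype(float)
    omega3 = 4.2 + 1.2 * fos + 0.6 * oily_fish + rng.normal(0.0, 1.2, size=n)

    # lifestyle / diet / medical covariates (model 2-4 adjustments)
    education = (rng.random(n) < 0.33).astype(float)
    tdi = rng.normal(-1.3, 3.0, size=n)
    bmi = rng.normal(27.3, 4.7, size=n)
    smoking = rng.choice(["never", "previous", "current"], size=n, p=[0.55, 0.35, 0.10])
    alcohol = rng.choice(["non", "low_moderate", "heavy"], size=n, p=[0.08, 0.72, 0.20])
    physical_activity = rng.gamma(2.0, 15.0, size=n)  # MET-h/week-ish
    diet3 = ["low", "medium", "high"]
    diet_oily_fish = np.asarray(diet3)[oily_fish_level.clip(0, 2)]
    diet_fruit = rng.choice(diet3, size=n, p=[0.3, 0.5, 0.2])
    diet_vegetable = rng.choice(diet3, size=n, p=[0.25, 0.55, 0.2])
    diet_processed_meat = rng.choice(["lt2_per_week", "ge2_per_week"], size=n, p=[0.6, 0.4])
    diet_red_meat = rng.choice(["lt2_per_week", "ge2_per_week"], size=n, p=[0.45, 0.55])
    suppl_vitamin = (rng.random(n) < 0.25).astype(float)
    suppl_mineral = (rng.random(n) < 0.15).astype(float)
    suppl_glucosamine = (rng.random(n) < 0.10).astype(float)
    hx = {
        "hx_hypertension": 0.27,
        "hx_cvd": 0.06,
        "hx_high_cholesterol": 0.13,
        "hx_diabetes": 0.05,
        "hx_depression": 0.06,
    }
    hx_cols = {k: (rng.random(n) < p).astype(float) for k, p in hx.items()}

    # APOE-defining SNP genotypes from haplotype draws
    haps = rng.choice(list(_APOE_HAP_FREQS), size=(n, 2),
                      p=list(_APOE_HAP_FREQS.values()))
    g429358 = ["".join(sorted(_APOE_HAP_ALLELES[h1][0] + _APOE_HAP_ALLELES[h2][0]))
               for h1, h2 in haps]
    g7412 = ["".join(sorted(_APOE_HAP_ALLELES[h1][1] + _APOE_HAP_ALLELES[h2][1]))
             for h1, h2 in haps]
    apoe_e4_true = (haps == "e4").sum(axis=1).astype(float)

    # linear predictor
    eta = np.zeros(n)
    cov_values = {"age": age - spec.age_mean, "sex": sex,
                  "education": education, "tdi": tdi, "bmi": bmi - np.mean(bmi),
                  "physical_activity": physical_activity - np.mean(physical_activity)}
    for k in range(10):
        cov_values[f"pc{k+1}"] = pcs[:, k]
    for name, b in spec.covariate_log_hrs.items():
        if name not in cov_values:
            raise KeyError(f"covariate_log_hrs refers to unknown covariate {name!r}")
        eta += b * cov_values[name]
    eta += spec.exposure_log_hr * fos
    dos = genos.mean_imputed()
    for j, b_main, b_int in spec.causal_effects:
        eta += b_main * dos[:, j] + b_int * dos[:, j] * fos
    eta += spec.apoe_log_hr_main * apoe_e4_true
    eta += spec.apoe_log_hr_interaction * apoe_e4_true * fos

    rate = spec.baseline_hazard_rate * np.exp(np.clip(eta, -500, 500))
    t_event = rng.exponential(1.0 / rate)
    time_years = np.minimum(t_event, spec.admin_censor_years)
    event = (t_event <= spec.admin_censor_years).astype(int)
    subtype = rng.choice(["ad", "vad", "other"], size=n, p=[0.55, 0.25, 0.20])
    event_ad = ((event == 1) & (subtype == "ad")).astype(int)
    event_vad = ((event == 1) & (subtype == "vad")).astype(int)

    table = pd.DataFrame({
        "sample_id": genos.sample_ids,
        "time_years": time_years,
        "event_dementia": event,
        "event_ad": event_ad,
        "event_vad": event_vad,
        "fos": fos,
        "fos_24h": fos_24h,
        "oily_fish": oily_fish,
        "omega3": omega3,
        "age": age,
        "sex": sex,
        **{f"pc{k+1}": pcs[:, k] for k in range(10)},
        "education": education,
        "tdi": tdi,
        "bmi": bmi,
        "smoking": smoking,
        "alcohol": alcohol,
        "physical_activity": physical_activity,
        "diet_oily_fish": diet_oily_fish,
        "diet_fruit": diet_fruit,
        "diet_vegetable": diet_vegetable,
        "diet_processed_meat": diet_processed_meat,
        "diet_red_meat": diet_red_meat,
        "suppl_vitamin": suppl_vitamin,
        "suppl_mineral": suppl_mineral,
        "suppl_glucosamine": suppl_glucosamine,
        **hx_cols,
        "rs429358": g429358,
        "rs7412": g7412,
        "apoe_e4_true": apoe_e4_true,
    })
    if spec.covariate_missing_rate > 0:
        rng_m = spec.rng(4)
        for col in ("education", "tdi", "bmi", "smoking", "alcohol",
                    "physical_activity"):
            mask = rng_m.random(n) < spec.covariate_missing_rate
            table.loc[mask, col] = np.nan
    return table


def write_fixture(genos: GenotypeMatrix, cohort: pd.DataFrame, out_dir: str | Path,
                  causal_effects: list[tuple[int, float, float]] | None = None) -> dict[str, Path]:
    """Write a simulated dataset as VCF (FORMAT DS) + phenotype TSV + truth TSV.

    Round-trips losslessly through :mod:`survgxe.dataio` readers up to the
    4-decimal dosage precision of the VCF text encoding.
    """
    from . import dataio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / "genotypes.vcf"
    pheno_path = out_dir / "phenotypes.tsv"
    truth_path = out_dir / "truth.tsv"
    dataio.write_vcf(genos, vcf_path)
    dataio.write_phenotypes(cohort, pheno_path)
    rows = []
    for j, b_main, b_int in (causal_effects or []):
        rows.append({"variant_id": genos.variants[j].id,
                     "beta_main": b_main, "beta_gxe": b_int})
    pd.DataFrame(rows, columns=["variant_id", "beta_main", "beta_gxe"]).to_csv(
        truth_path, sep="\t", index=False, float_format="%.10g")
    return {"vcf": vcf_path, "phenotypes": pheno_path, "truth": truth_path}
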