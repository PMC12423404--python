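# Methods

## The problem

Dietary supplements such as fish oil show modest average associations with
dementia incidence in prospective cohorts, but an average effect can hide
genotype-dependent heterogeneity: a variant may make the supplement
protective in some carriers and harmful in others. Detecting such
gene-environment (G×E) interactions genome-wide by fitting an interaction
model at every variant is statistically and computationally wasteful. This
package implements a **two-step screen** on time-to-event data:

1. **Discovery.** Survival GWAS of the outcome in the full cohort *and
   separately within each exposure stratum*, using a fast Cox score test.
   Variants reaching a lenient suggestive threshold (p < 1e-5, MAF > 0.01)
   in any of the three scans become candidates. Stratified discovery is the
   crux: a pure crossover interaction (hazardous when exposed, protective
   when unexposed) has a near-zero marginal effect and is invisible to the
   overall scan, but is a plain main effect within a stratum.
2. **Confirmation.** Candidates are collapsed into independent loci by LD
   clumping (r² < 0.1 within 250 kb) with ±250-kb extension; the locus
   count sets a Bonferroni threshold (0.05 / n_loci); each candidate is
   then tested in a Cox model with a SNP×exposure product term, and
   significant loci are profiled by subgroup hazard ratios, nearest-gene
   annotation, alternative-exposure replication, and covariate-sensitivity
   comparison across four adjustment models.

## Cox engine

All survival models are Cox proportional-hazards fits maximizing the
Efron-tie-corrected log partial likelihood by Newton-Raphson with
step-halving. Efron's correction is the default because real biobank
follow-up times (recorded in days, or as ages) tie frequently; on the
untied continuous times the generator produces it reduces to the exact
partial likelihood. Convergence is declared when the relative change in
log partial likelihood falls below 1e-9 (max 50 iterations), after which
one extra Newton step is taken so coefficients are at machine precision —
this is what lets the test suite demand 1e-6 agreement with an independent
implementation. Near-singular information matrices get a 1e-8 ridge;
coefficients exceeding |β| > 15 abort with a separation error advising
penalization (exp(15) is far beyond any real hazard ratio). Identically
zero covariate columns are pinned at β = 0 (they carry no information);
non-zero constant columns and exact collinearity (checked after centering,
since the partial likelihood is shift-invariant) are rejected with the
offending columns named.

The baseline cumulative hazard uses the Breslow estimator, giving
martingale residuals r_i = δ_i − Λ̂₀(t_i)·exp(x_iᵀβ̂) that sum to zero
exactly at any β — the suite asserts this at every converged fit.
Single-coefficient inference is Wald (z = β̂/SE, 95% CI as exp(β̂ ± 1.96·SE)),
matching how interaction effects and subgroup hazard ratios are reported;
a likelihood-ratio test is available as a diagnostic.

### Model presets

* **model1** — age, sex, PC1–PC10 (also the GWAS null covariates);
* **model2** — + education, Townsend deprivation index, BMI, smoking,
  alcohol, physical activity;
* **model3** — + 8 dietary variables;
* **model4** — + 5 medical-history flags.

Unordered categorical covariates are dummy-encoded against their first
sorted level. Continuous exposures (circulating ω-3) are standardized to
mean 0, SD 1 before the product term is formed, so the interaction
coefficient is per-SD and numerically well scaled.

## Score test and saddlepoint approximation

Per-variant testing refits nothing. From a single null fit per
(outcome, stratum):

* missing dosages are mean-imputed per variant;
* the dosage g is residualized on the null covariates plus an intercept
  (least-squares projection), giving g̃;
* the score is S = Σ g̃_i·r_i with r the null-model martingale residuals;
* the variance is the exact genotype-permutation variance
  V = (Σ g̃_i²)(Σ r_i²)/(n−1), so z = S/√V has permutation-calibrated
  mean 0 and variance 1 under the null by construction.

With rare events the residual distribution is extremely skewed (a few
values near +1, a mass of small negatives), so normal tail probabilities
are anti-conservative exactly where GWAS significance is decided. Beyond
|z| > 2 (the conventional hybrid switch; below it the normal and
saddlepoint tails agree to within a few percent) the tail is recomputed
from the score's null cumulant generating function, treating residuals as
fixed and each sample's genotype as an independent Hardy-Weinberg draw
centered at its mean 2p̂:

K(t) = Σ_i log[ q̂²·e^{−2p̂·t·r_i} + 2p̂q̂·e^{(1−2p̂)·t·r_i} + p̂²·e^{(2−2p̂)·t·r_i} ]

The observed score is rescaled by √(K″(0)/V) so the CGF's variance matches
the test's variance (the projection residualization slightly shrinks Σ g̃²
relative to raw genotypes). The saddlepoint K′(ζ) = s is bracketed by
doubling and solved with Brent's method; each one-sided tail uses the
Lugannani–Rice formula

w = sign(ζ)·√(2(ζs − K(ζ))),  v = ζ·√(K″(ζ)),
P ≈ 1 − Φ(w) − φ(w)·(1/w − 1/v),

with the Barndorff-Nielsen form as numerical fallback and the two-sided p
the sum of both tails. Degenerate cases (|w| < 1e-5) fall back to the
normal tail; an unreachable saddlepoint (score outside the null support)
falls back to the normal p and is flagged `spa_failed_fallback`.
Correctness is anchored to a 200,000-draw genotype-permutation oracle on a
rare-event fixture, not to any external implementation; the global-null
suite checks type-I error at α = 0.01 within the 99% binomial band and
that SPA beats the normal approximation at α = 1e-3 under ~1% events.

## Quality control

Variant filters run in a fixed order so removal attribution is
deterministic: imputation info < 0.3 → non-biallelic → MAF < 0.001 →
call rate < 95% → HWE exact p < 1e-8 (on hard calls; dosages round half to
even at class boundaries). Samples with call rate < 98% are then dropped.
The HWE test is the exact conditional test (sum of probabilities of all
heterozygote counts, given the allele counts, no larger than the
observed count's probability); it matches an exact-rational enumeration
oracle for all totals ≤ 200. Relatedness pruning removes samples in more
than 10 third-degree-or-closer pairs (kinship > 0.0442) first, then walks
the remaining pairs in sorted order removing one member uniformly at
random (seeded). The stricter MAF > 0.01 filter applies only at candidate
selection.

## Loci

Clumping is PLINK-style greedy: candidates by ascending p (ties: position,
then id); a variant joins the best-p existing index within 250 kb
(index-to-variant distance) at in-sample r² ≥ 0.1, otherwise it founds its
own clump — proximity without correlation is not membership. Merging is
span-to-span: clumps whose member spans lie within 250 kb merge
transitively (union semantics; idempotent). Extension pads ±250 kb,
floors starts at 1, and merges overlapping extended intervals before
counting independent loci. Coordinates are 1-based inclusive internally;
BED input converts from 0-based half-open. The greedy partition is checked
exactly against a brute-force oracle on 100 random ≤50-variant instances.
The Bonferroni denominator pools merged, extended candidate loci across
outcomes into a single count, and per-outcome counts are also reported.

Nearest-gene annotation considers protein-coding entries only; distance is
0 inside the gene span, otherwise the smaller endpoint distance; exact
ties resolve to the smaller start, then the lexicographically smaller
symbol.

## Cohort preparation

Exposure coders are total on their declared vocabularies and raise on
anything else. Fish-oil supplementation is 1 iff the fish-oil option was
selected, 0 for other supplements or "none of the above", missing for no
response. Oily-fish intake dichotomizes at once a week (never / less than
once a week → low).

APOE ε4 dosage resolves the unphased rs429358/rs7412 diplotype into its
two possible haplotype pairings (ε2 = T-T, ε3 = T-C, ε4 = C-C, ε1 = C-T in
rs429358-rs7412 order) and returns the ε4 count when both pairings agree.
The double heterozygote (CT, CT) is ambiguous between ε1/ε3 and ε2/ε4 and
is excluded, as are missing genotypes. The full 3×3 truth table is
asserted exhaustively in the suite.

Missing covariates are completed by a single chained-equations imputation:
predictive mean matching (linear regression, donor among the k = 5 nearest
predicted observed values) for continuous covariates, logistic-regression
Bernoulli draws for binaries, multinomial-logistic draws for unordered
categoricals; 10 sweeps in ascending-missingness order over a
mean/mode-initialized table. A single completed dataset (rather than
multiple imputations with pooling) keeps the downstream per-SNP fits
simple; the seed argument makes the completion reproducible, and nothing
observed is ever altered. Covariates over 50% missing trigger a warning;
fully missing ones are an error.

## Synthetic cohort generator

The generator produces the statistical structure the screen assumes, not a
biologically realistic genome:

* **Genotypes.** Allele frequencies uniform on a configurable MAF range;
  within blocks, latent Gaussians follow an AR(1) copula (correlation
  `ld_rho`) thresholded at the Hardy-Weinberg genotype-class quantiles, so
  marginals are exactly HWE while adjacent variants share tunable LD.
  Missing calls are MCAR.
* **Cohort.** Entry age truncated-normal on [40, 69] with the underlying
  location/scale solved so the *post-truncation* moments are the target
  mean 56.81 and SD 8.01; sex Bernoulli(0.5); ten standard-normal
  synthetic PCs; binary exposure with prevalence 0.317 (optionally
  age/sex-dependent to exercise confounding adjustment); correlated
  alternative exposures (24-h-recall status, oily-fish intake, continuous
  ω-3); lifestyle/diet/medical covariates for models 2–4 (no hazard effect
  by default, so they are pure noise adjustments); APOE-defining SNP
  genotypes drawn from haplotype frequencies ε2/ε3/ε4 = 0.08/0.77/0.15.
* **Event times.** Exponential given the linear predictor (constant
  baseline hazard, default 0.0015/person-year — a low dementia-like rate),
  administratively censored at 13.8 years, so time-on-study is the Cox
  timescale and entry age is a covariate. Age enters centered, keeping the
  baseline rate interpretable. Events are split 55/25/20% into
  Alzheimer's/vascular/other subtypes sharing one follow-up time.
* **Planted effects.** Per-variant main and interaction log-hazard ratios
  enter the linear predictor additively in dosage and dosage×exposure.

One integer seed drives everything through independently spawned streams;
identical specs give byte-identical outputs. What the generator does *not*
emulate: haplotype-panel LD, population stratification, informative
censoring, competing risks, age-varying hazards, exposure measurement
error correlated with outcome. Passing tests therefore demonstrate the
statistical machinery is correct under the model's assumptions, not that
real-cohort findings would replicate.

## Problem sizes in the test suite

The suite regenerates all data at run time. Sizes were chosen as the
smallest that make each check statistically decisive: global-null
calibration uses one n = 2,000 cohort per event rate with 50,000 null
variant tests; the permutation oracle uses n = 300 with 200,000
permutations; interaction-recovery uses 200 replicates at n = 20,000;
the two-step premise 100 replicates at n = 20,000; null-interaction
uniformity 2,500 replicate fits at n = 1,000; the end-to-end screens use
n ≈ 4,000–5,000 cohorts with ~100 variants. The acceptance script uses
somewhat smaller replicate counts (reported in its output alongside each
value) since it reports point estimates rather than pass/fail bands.

## Known limitations

* The score-test variance is permutation-based (robust), not the
  model-based information variance; the two agree under the null but can
  differ under strong covariate-genotype correlation.
* The SPA treats the projection residualization only through a variance
  rescaling; with very many covariates relative to n the genotype-skew
  model becomes approximate.
* Single imputation understates covariate-imputation uncertainty in
  downstream standard errors.
* In-sample LD only; no reference-panel r².
* The replication rule (p < 0.05 and sign concordance with the primary
  coefficient) is a package decision; both components are emitted so other
  rules can be recomputed.
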