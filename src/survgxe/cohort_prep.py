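"""Exposure/outcome coding, APOE e4 dosage, and covariate imputation.

Turns raw questionnaire and genotype inputs into the analysis-ready columns
the interaction models expect: binary fish-oil supplementation (FOS), the
low/high oily-fish intake grouping, the APOE epsilon-4 haplotype dosage with
exclusion of the ambiguous double-heterozygote, and a single completed
covariate table from chained-equations imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SUPPLEMENT_OPTIONS", "OILY_FISH_LEVELS", "EXCLUDED",
    "derive_fos_status", "derive_oily_fish_group", "apoe_e4_dosage",
    "impute_covariates", "load_coding_map", "recode_columns",
]


def load_coding_map(path) -> dict[str, dict[str, str]]:
    """Read a YAML questionnaire coding map: {column: {raw string: level}}."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not all(isinstance(v, dict) for v in mapping.values()):
        raise ValueError("coding map must be a mapping of column -> {raw: level}")
    return mapping


def recode_columns(table: pd.DataFrame, mapping: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Recode raw questionnaire strings to canonical levels; unknown raw
    values raise with the offending column and value named."""
    out = table.copy()
    for col, codes in mapping.items():
        if col not in out.columns:
            raise KeyError(f"coding map column {col!r} not in table")
        s = out[col]
        unknown = set(s.dropna().unique()) - set(codes)
        if unknown:
            raise ValueError(f"unknown values in {col!r}: {sorted(unknown)[:5]}")
        out[col] = s.map(codes).where(s.notna(), other=np.nan)
    return out

# Touchscreen supplement-question vocabulary; the fish-oil option defines
# the exposure, everything else (or "none of the above") codes unexposed.
SUPPLEMENT_OPTIONS = frozenset({
    "fish oil (including cod liver oil)",
    "glucosamine",
    "calcium",
    "zinc",
    "iron",
    "selenium",
    "none of the above",
})
_FISH_OIL = "fish oil (including cod liver oil)"

OILY_FISH_LEVELS = (
    "never",
    "less than once a week",
    "once a week",
    "2-4 times a week",
    "5-6 times a week",
    "once or more daily",
)
_LOW_INTAKE = {"never", "less than once a week"}

#: sentinel returned for samples excluded from APOE e4 dosage assignment
EXCLUDED = "excluded"


def derive_fos_status(selected_options: set[str] | frozenset[str]) -> float:
    """Code fish-oil supplementation: 1 if the fish-oil option was selected,
    0 if only other supplements or "none of the above", NaN for no response."""
    unknown = set(selected_options) - SUPPLEMENT_OPTIONS
    if unknown:
        raise ValueError(f"unknown questionnaire option(s): {sorted(unknown)}")
    if not selected_options:
        return float("nan")
    return 1.0 if _FISH_OIL in selected_options else 0.0


def derive_oily_fish_group(frequency_level: str) -> int:
    """Dichotomize 6-level oily-fish intake: never / <1 per week -> low (0),
    all higher frequencies -> high (1)."""
    if frequency_level not in OILY_FISH_LEVELS:
        raise ValueError(f"unknown oily-fish frequency level {frequency_level!r}")
    return 0 if frequency_level in _LOW_INTAKE else 1


def _normalize_genotype(g) -> str | None:
    if g is None or (isinstance(g, float) and np.isnan(g)):
        return None
    s = "".join(sorted(str(g).upper().replace("/", "")))
    if len(s) != 2 or any(a not in "CT" for a in s):
        return None
    return s


# epsilon haplotypes keyed by (rs429358 allele, rs7412 allele)
_HAPLOTYPE = {("T", "T"): "e2", ("T", "C"): "e3", ("C", "C"): "e4", ("C", "T"): "e1"}


def apoe_e4_dosage(g_rs429358, g_rs7412) -> int | str:
    """Count epsilon-4 haplotypes from unphased rs429358/rs7412 genotypes.

    The unphased diplotype is resolved into the two possible haplotype
    pairings; if both pairings imply the same e4 count, that count (0/1/2)
    is returned. The double heterozygote (CT, CT) is ambiguous between
    e1/e3 and e2/e4 and returns :data:`EXCLUDED`, as does any missing or
    malformed genotype.
    """
    a = _normalize_genotype(g_rs429358)
    b = _normalize_genotype(g_rs7412)
    if a is None or b is None:
        return EXCLUDED
    pairings = {
        (_HAPLOTYPE[(a[0], b[0])], _HAPLOTYPE[(a[1], b[1])]),
        (_HAPLOTYPE[(a[0], b[1])], _HAPLOTYPE[(a[1], b[0])]),
    }
    counts = {sum(h == "e4" for h in pair) for pair in pairings}
    if len(counts) > 1:
        return EXCLUDED
    return counts.pop()


def apoe_e4_dosage_column(table: pd.DataFrame) -> pd.Series:
    """Vectorized e4 dosage over 'rs429358'/'rs7412' columns; excluded -> NaN."""
    out = [apoe_e4_dosage(a, b) for a, b in zip(table["rs429358"], table["rs7412"])]
    return pd.Series([np.nan if v == EXCLUDED else float(v) for v in out],
                     index=table.index, name="apoe_e4_dosage")


# ---------------------------------------------------------------------------
# chained-equations covariate imputation


def _column_kind(s: pd.Series) -> str:
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return "categorical"
    obs = s.dropna().unique()
    if len(obs) <= 2:
        return "binary"
    return "continuous"


def impute_covariates(
    table: pd.DataFrame,
    seed: int = 0,
    columns: list[str] | None = None,
    k_pmm: int = 5,
    n_iter: int = 10,
) -> pd.DataFrame:
    """Single chained-equations imputation of missing covariate values.

    Continuous covariates are imputed by predictive mean matching (linear
    regression, donor drawn among the ``k_pmm`` nearest predicted observed
    values), binary covariates by logistic-regression Bernoulli draws, and
    unordered categoricals by multinomial-logistic draws. Columns are
    visited in order of ascending missingness for ``n_iter`` sweeps over a
    mean/mode-initialized table. Observed values are never altered; the
    result is deterministic given ``seed``.

    A covariate with more than 50% missing triggers a warning; a fully
    missing covariate is an error.
    """
    from sklearn.linear_model import LinearRegression, LogisticRegression

    rng = np.random.default_rng(seed)
    out = table.copy()
    if columns is None:
        skip = {"sample_id", "time_years"}
        skip |= {c for c in out.columns if c.startswith("event_")}
        columns = [c for c in out.columns
                   if c not in skip and out[c].isna().any()]
    columns = [c for c in columns if out[c].isna().any()]
    if not columns:
        return out
    kinds = {}
    for c in columns:
        frac = out[c].isna().mean()
        if frac >= 1.0:
            raise ValueError(f"covariate {c!r} is fully missing; cannot impute")
        if frac > 0.5:
            logger.warning("covariate %s is %.0f%% missing", c, 100 * frac)
        kinds[c] = _column_kind(out[c])
    order = sorted(columns, key=lambda c: (out[c].isna().mean(), c))
    miss_mask = {c: out[c].isna().to_numpy() for c in order}

    # predictor pool: every other covariate-ish numeric/categorical column
    pool = [c for c in out.columns
            if c not in ("sample_id",) and not c.startswith("event_")]

    work = out.copy()
    for c in pool:
        if work[c].isna().any():
            if _column_kind(work[c]) in ("categorical",):
                mode = work[c].mode(dropna=True)
                work[c] = work[c].fillna(mode.iloc[0])
            else:
                work[c] = work[c].fillna(work[c].median())

    def predictors(target: str) -> np.ndarray:
        cols = []
        for c in pool:
            if c == target:
                continue
            s = work[c]
            if _column_kind(out[c] if c in out else s) == "categorical" or s.dtype == object:
                for lev in sorted(pd.unique(s))[1:]:
                    cols.append((s == lev).to_numpy(dtype=float))
            else:
                x = s.to_numpy(dtype=float)
                sd = x.std()
                cols.append((x - x.mean()) / (sd if sd > 0 else 1.0))
        return np.column_stack(cols) if cols else np.zeros((len(work), 1))

    for _ in range(n_iter):
        for c in order:
            mask = miss_mask[c]
            X = predictors(c)
            Xo, Xm = X[~mask], X[mask]
            yo = out.loc[~mask, c]
            kind = kinds[c]
            if kind == "continuous":
                reg = LinearRegression().fit(Xo, yo.to_numpy(dtype=float))
                pred_o = reg.predict(Xo)
                pred_m = reg.predict(Xm)
                donors = yo.to_numpy(dtype=float)
                filled = np.empty(len(pred_m))
                k = min(k_pmm, len(donors))
                for i, pm in enumerate(pred_m):
                    near = np.argpartition(np.abs(pred_o - pm), k - 1)[:k]
                    filled[i] = donors[near[rng.integers(k)]]
                work.loc[mask, c] = filled
            else:
                y = yo.astype(str).to_numpy() if kind == "categorical" else yo.to_numpy(dtype=float)
                classes = np.unique(y)
                if len(classes) < 2:
                    work.loc[mask, c] = classes[0]
                else:
                    clf = LogisticRegression(max_iter=500).fit(Xo, y)
                    proba = clf.predict_proba(Xm)
                    cum = np.cumsum(proba, axis=1)
                    u = rng.random(len(Xm))
                    pick = (u[:, None] > cum).sum(axis=1)
                    work.loc[mask, c] = clf.classes_[pick]
    for c in order:
        out.loc[miss_mask[c], c] = work.loc[miss_mask[c], c]
        if kinds[c] != "categorical":
            out[c] = out[c].astype(float)
    return out
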