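"""Cox proportional-hazards engine.

Fits right-censored Cox models by Newton-Raphson maximization of the
Efron-tie-corrected log partial likelihood and exposes the machinery the
genome-wide scan and the interaction screen both build on: coefficient
covariance, Breslow baseline cumulative hazard, martingale residuals, Wald
and likelihood-ratio tests, and the named covariate presets (models 1-4)
used throughout the interaction analysis.

The fit keeps the design matrix and a QR factorization of the
intercept-augmented covariates so that downstream per-variant score tests
can residualize genotype vectors cheaply without refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NullCoxFit",
    "WaldResult",
    "MODEL_PRESETS",
    "model_terms",
    "build_design",
    "fit_cox",
    "wald_test",
    "lrt",
]

# Covariate presets mirroring the four interaction models: model 1 adjusts
# for age, sex and the top 10 genetic PCs; model 2 adds socioeconomic and
# lifestyle factors; model 3 adds 8 dietary patterns; model 4 adds 5
# self-reported medical histories.
_PCS = [f"pc{i}" for i in range(1, 11)]
MODEL_PRESETS: dict[str, list[str]] = {
    "model1": ["age", "sex", *_PCS],
    "model2": ["age", "sex", *_PCS, "education", "tdi", "bmi", "smoking",
               "alcohol", "physical_activity"],
    "model3": ["age", "sex", *_PCS, "education", "tdi", "bmi", "smoking",
               "alcohol", "physical_activity",
               "diet_oily_fish", "diet_fruit", "diet_vegetable",
               "diet_processed_meat", "diet_red_meat",
               "suppl_vitamin", "suppl_mineral", "suppl_glucosamine"],
    "model4": ["age", "sex", *_PCS, "education", "tdi", "bmi", "smoking",
               "alcohol", "physical_activity",
               "diet_oily_fish", "diet_fruit", "diet_vegetable",
               "diet_processed_meat", "diet_red_meat",
               "suppl_vitamin", "suppl_mineral", "suppl_glucosamine",
               "hx_hypertension", "hx_cvd", "hx_high_cholesterol",
               "hx_diabetes", "hx_depression"],
}


def model_terms(model: int | str) -> list[str]:
    """Return the covariate list for a preset given as 1-4 or 'model1'..'model4'."""
    key = f"model{model}" if isinstance(model, int) else str(model)
    if key not in MODEL_PRESETS:
        raise KeyError(f"unknown model preset {model!r}")
    return list(MODEL_PRESETS[key])


def build_design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Assemble a numeric design matrix from covariate names and 'a:b' products.

    Unordered categorical columns (object or pandas categorical dtype) are
    dummy-encoded against their first (sorted) level; numeric columns enter
    as-is. Product terms 'a:b' multiply two numeric columns.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            xa = _numeric_column(table, a)
            xb = _numeric_column(table, b)
            cols.append(xa * xb)
            names.append(term)
            continue
        if term not in table.columns:
            raise KeyError(f"covariate {term!r} not in table")
        s = table[term]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna()))
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{term}={lev}")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
    if not cols:
        return np.empty((len(table), 0)), []
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        bad = [names[j] for j in np.unique(np.where(~np.isfinite(X))[1])]
        raise ValueError(f"non-finite values in design columns {bad}")
    return X, names


def _numeric_column(table: pd.DataFrame, name: str) -> np.ndarray:
    if name not in table.columns:
        raise KeyError(f"covariate {name!r} not in table")
    s = table[name]
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        raise ValueError(f"product terms require numeric columns; {name!r} is categorical")
    return s.to_numpy(dtype=float)


@dataclass
class WaldResult:
    """Single-coefficient Wald test: log-HR, SE, z, two-sided p, HR and 95% CI."""

    term: str
    beta: float
    se: float
    z: float
    p: float
    hr: float
    ci95: tuple[float, float]


@dataclass
class NullCoxFit:
    """A converged Cox partial-likelihood fit plus score-test machinery."""

    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    baseline_times: np.ndarray      # unique event times, ascending
    cum_baseline_hazard: np.ndarray  # Breslow estimator at baseline_times
    martingale_residuals: np.ndarray  # per sample, input order
    time: np.ndarray
    event: np.ndarray
    X: np.ndarray                   # design matrix, input order
    _q_aug: np.ndarray | None = field(default=None, repr=False)

    def cumhaz_at(self, t: np.ndarray) -> np.ndarray:
        """Breslow cumulative baseline hazard evaluated at times ``t``."""
        idx = np.searchsorted(self.baseline_times, t, side="right")
        ch = np.concatenate([[0.0], self.cum_baseline_hazard])
        return ch[idx]

    def residualize(self, g: np.ndarray) -> np.ndarray:
        """Project out the covariates (plus intercept) from a vector/matrix."""
        if self._q_aug is None:
            aug = np.column_stack([np.ones(self.n), self.X])
            q, _ = np.linalg.qr(aug)
            self._q_aug = q
        q = self._q_aug
        return g - q @ (q.T @ g)


def _resolve_outcome(table: pd.DataFrame, outcome: str, time_col: str) -> tuple[np.ndarray, np.ndarray]:
    if outcome in table.columns:
        ev_col = outcome
    elif f"event_{outcome}" in table.columns:
        ev_col = f"event_{outcome}"
    else:
        raise KeyError(f"no event column for outcome {outcome!r}")
    time = table[time_col].to_numpy(dtype=float)
    event = table[ev_col].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(int)


def _check_design(X: np.ndarray, names: list[str]) -> np.ndarray:
    """Validate estimability; return boolean mask of active (free) columns.

    Identically-zero columns carry no information and are pinned at
    coefficient 0. Non-zero constant columns and exact collinearity (after
    centering, since the partial likelihood is invariant to column shifts)
    are rejected with the offending columns named.
    """
    active = np.ones(X.shape[1], dtype=bool)
    for j, name in enumerate(names):
        col = X[:, j]
        if np.all(col == 0.0):
            active[j] = False
            logger.warning("covariate %s is identically zero; coefficient pinned at 0", name)
        elif np.ptp(col) == 0.0:
            raise ValueError(f"constant covariate column {name!r} is not estimable in a Cox model")
    Xa = X[:, active]
    if Xa.shape[1] > 1:
        Xc = Xa - Xa.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xa.shape[1]:
            # name dependent columns via pivoted QR
            from scipy.linalg import qr as _qr

            _, _, piv = _qr(Xc, mode="economic", pivoting=True)
            dep = sorted(np.asarray(names, dtype=object)[active][piv[rank:]])
            raise ValueError(f"exactly collinear covariate columns detected: {list(dep)}")
    return active


class _EfronLikelihood:
    """Log partial likelihood, gradient, and information with Efron ties.

    Samples are pre-sorted by ascending time; risk sets are suffixes. Tie
    groups of d events are expanded into d Efron sub-steps; suffix sums and
    grouped reductions keep every Newton iteration O(n p + E p^2).
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray):
        order = np.argsort(time, kind="stable")
        self.order = order
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.X = np.ascontiguousarray(X[order])
        self.n, self.p = self.X.shape
        ev_idx = np.flatnonzero(self.event)
        self.ev_idx = ev_idx
        ev_times = self.time[ev_idx]
        self.event_times, starts, self.d = np.unique(
            ev_times, return_index=True, return_counts=True
        )
        self.group_starts = starts  # into ev_idx
        self.K = len(self.event_times)
        self.E = len(ev_idx)
        # first at-risk index per event time (risk set = suffix from there)
        self.risk_start = np.searchsorted(self.time, self.event_times, side="left")
        # expanded Efron sub-step bookkeeping
        rep = np.repeat(np.arange(self.K), self.d)
        l_within = np.arange(self.E) - np.repeat(starts, self.d)
        self.rep = rep
        self.frac = l_within / self.d[rep].astype(float)
        # per-sample group index of event samples (position in sorted order)
        self.ev_group = rep  # ev_idx[i] belongs to group rep[i] (ev_idx sorted by time)
        self.sum_x_events = self.X[ev_idx].sum(axis=0)

    def _suffix(self, arr: np.ndarray) -> np.ndarray:
        return np.cumsum(arr[::-1], axis=0)[::-1]

    def loglik_grad_info(self, beta: np.ndarray, want_hessian: bool = True):
        X, n, p = self.X, self.n, self.p
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        wx = w[:, None] * X
        s0_suffix = self._suffix(w)
        s1_suffix = self._suffix(wx)
        S0 = s0_suffix[self.risk_start]
        S1 = s1_suffix[self.risk_start]
        w_ev = w[self.ev_idx]
        wx_ev = wx[self.ev_idx]
        s0d = np.add.reduceat(w_ev, self.group_starts)
        s1d = np.add.reduceat(wx_ev, self.group_starts, axis=0)
        rep, frac = self.rep, self.frac
        D = S0[rep] - frac * s0d[rep]
        num = S1[rep] - frac[:, None] * s1d[rep]
        if np.any(D <= 0):
            return -np.inf, None, None
        ll = float(eta[self.ev_idx].sum() - np.log(D).sum())
        num_over_D = num / D[:, None]
        grad = self.sum_x_events - num_over_D.sum(axis=0)
        if not want_hessian:
            return ll, grad, None
        inv_D = 1.0 / D
        c = np.add.reduceat(inv_D, self.group_starts)            # per group
        b = np.add.reduceat(frac * inv_D, self.group_starts)     # per group
        cum_c = np.concatenate([[0.0], np.cumsum(c)])
        pos = np.searchsorted(self.event_times, self.time, side="right")
        dweight = w * cum_c[pos]
        dweight_ev = dweight[self.ev_idx] - w_ev * b[self.ev_group]
        dw = dweight.copy()
        dw[self.ev_idx] = dweight_ev
        H1 = (X * dw[:, None]).T @ X
        H2 = num_over_D.T @ num_over_D / 1.0
        # note: sum num num^T / D^2 = (num/D)^T (num/D)
        info = H1 - H2
        return ll, grad, info

    def breslow(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eta = np.clip(self.X @ beta, -500, 500)
        w = np.exp(eta)
        S0 = self._suffix(w)[self.risk_start]
        cumhaz = np.cumsum(self.d / S0)
        return self.event_times, cumhaz


def fit_cox(
    table: pd.DataFrame,
    terms: list[str],
    outcome: str = "dementia",
    time_col: str = "time_years",
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 1e-8,
) -> NullCoxFit:
    """Fit a Cox proportional-hazards model by penalized-free Newton-Raphson.

    ``terms`` are covariate column names, with 'a:b' denoting a product of
    two numeric columns; categorical columns are dummy-encoded. Convergence
    is declared when the relative change in log partial likelihood falls
    below ``tol`` (default 1e-9), with step-halving to keep the likelihood
    non-decreasing and a small ridge fallback for near-singular information.

    Raises on datasets without events, constant or exactly collinear
    columns, and monotone likelihood (separation).
    """
    time, event = _resolve_outcome(table, outcome, time_col)
    if event.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    X, names = build_design(table, terms)
    active = _check_design(X, names)
    n, p = X.shape
    lik = _EfronLikelihood(time, event, X[:, active])
    pa = int(active.sum())
    beta_a = np.zeros(pa)
    ll, grad, info = lik.loglik_grad_info(beta_a)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if pa == 0:
            converged = True
            break
        H = info
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = info + ridge * np.eye(pa)
            step = np.linalg.solve(H, grad)
        # step-halving line search
        scale = 1.0
        for _ in range(40):
            cand = beta_a + scale * step
            ll_new, grad_new, info_new = lik.loglik_grad_info(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            logger.warning("step-halving failed to improve likelihood at iter %d", it)
            break
        delta = ll_new - ll
        beta_a, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta_a)) > 15:  # exp(15) ~ 3e6: no real hazard ratio
            raise ValueError(
                "monotone partial likelihood (separation) detected: coefficients "
                "diverging; consider penalized estimation or removing the covariate"
            )
        if abs(delta) < tol * (abs(ll) + 1.0):
            converged = True
            # one refinement step: Newton is quadratic, so this takes the
            # solution to machine precision once the ll has stabilized
            try:
                beta_a = beta_a + np.linalg.solve(info, grad)
                ll, grad, info = lik.loglik_grad_info(beta_a)
            except np.linalg.LinAlgError:
                pass
            break
    if not converged:
        logger.warning("Cox fit did not converge in %d iterations (|dll|=%.3g)", it, abs(delta))
    if pa:
        try:
            cov_a = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov_a = np.linalg.inv(info + ridge * np.eye(pa))
    else:
        cov_a = np.zeros((0, 0))
    beta = np.zeros(p)
    beta[active] = beta_a
    cov = np.zeros((p, p))
    cov[np.ix_(active, active)] = cov_a
    bt, ch = lik.breslow(beta_a)
    # martingale residuals in input order
    eta_full = X[:, active] @ beta_a
    idx = np.searchsorted(bt, time, side="right")
    ch0 = np.concatenate([[0.0], ch])
    resid = event - ch0[idx] * np.exp(np.clip(eta_full, -500, 500))
    return NullCoxFit(
        terms=names,
        beta=beta,
        cov=cov,
        log_partial_likelihood=ll,
        n=n,
        n_events=int(event.sum()),
        converged=converged,
        n_iter=it,
        baseline_times=bt,
        cum_baseline_hazard=ch,
        martingale_residuals=resid,
        time=time,
        event=event,
        X=X,
    )


def wald_test(fit: NullCoxFit, term: str) -> WaldResult:
    """Wald test for one coefficient: z = beta/SE, two-sided normal p,
    with HR and 95% CI on the exponentiated scale."""
    if term not in fit.terms:
        raise KeyError(f"term {term!r} not in fitted model ({fit.terms})")
    j = fit.terms.index(term)
    beta = float(fit.beta[j])
    var = float(fit.cov[j, j])
    se = float(np.sqrt(var)) if var > 0 else 0.0
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return WaldResult(term=term, beta=beta, se=se, z=z, p=p, hr=hr, ci95=ci)


def lrt(full: NullCoxFit, reduced: NullCoxFit) -> float:
    """Likelihood-ratio test p-value for nested Cox fits on the same samples."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model terms must be a subset of the full model")
    if full.n != reduced.n or full.n_events != reduced.n_events:
        raise ValueError("nested models must be fit on the same samples")
    df = len(full.terms) - len(reduced.terms)
    if df == 0:
        return 1.0
    stat = 2.0 * (full.log_partial_likelihood - reduced.log_partial_likelihood)
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df))
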