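"""Sex-stratified Weibull proportional hazards on the age timescale.

Model
-----
Attained age is the timescale.  For a subject of sex ``s`` with covariate
vector ``x`` the hazard of fatal CVD at age ``t`` is

    h(t | x) = exp(alpha_s) * p_s * t**(p_s - 1) * exp(beta @ x)

so the cumulative baseline hazard is ``H0_s(t) = exp(alpha_s) * t**p_s``.
Baseline age enters as delayed entry (left truncation): a subject examined at
age ``a0`` contributes risk only on ``(a0, exit]``, and the likelihood
conditions on survival to ``a0``.  There is no age coefficient — age acts
through the baseline hazard, which is what lets a single fitted model yield
absolute risks at any age and any horizon.

The absolute risk of the event within ``h`` years for a subject event-free at
age ``a0`` is

    risk = 1 - S(a0 + h | x) / S(a0 | x)
         = 1 - exp(-(H0(a0 + h) - H0(a0)) * exp(beta @ x)).

Both sexes share the coefficient vector ``beta``; the intercept ``alpha_s``
and shape ``p_s`` are stratum-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .cohort import SEX_LABELS, CohortTable, RiskFactorProfile

logger = logging.getLogger(__name__)

#: Covariates a model may use, in canonical order.
MODEL_COVARIATES = ("smoking", "sbp", "glucose", "cholesterol", "diabetes")


@dataclass
class WeibullPHModel:
    """Stratum baseline parameters plus shared log-hazard-ratio coefficients.

    ``alpha`` and ``shape`` map stratum label -> parameter; ``beta`` maps
    covariate name -> per-unit log hazard ratio (smoking and diabetes are
    indicator covariates).
    """

    alpha: dict[str, float]
    shape: dict[str, float]
    beta: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.alpha) != set(self.shape):
            raise ValueError("alpha and shape must cover the same strata")
        for s, p in self.shape.items():
            if not p > 0:
                raise ValueError(f"shape must be > 0 in stratum {s!r}, got {p}")
        for name in self.beta:
            if name not in MODEL_COVARIATES:
                raise ValueError(f"unknown covariate in beta: {name!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.beta)

    def linear_predictor(self, profile: RiskFactorProfile | Mapping) -> float:
        return linear_predictor(self, profile)

    def predict_absolute_risk(
        self, profile: RiskFactorProfile | Mapping, horizon: float = 10.0
    ) -> float:
        return predict_absolute_risk(self, profile, horizon)

    def to_dict(self) -> dict:
        return {"alpha": dict(self.alpha), "shape": dict(self.shape),
                "beta": dict(self.beta)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeibullPHModel":
        return cls(alpha=dict(d["alpha"]), shape=dict(d["shape"]),
                   beta=dict(d["beta"]))


@dataclass
class FitResult:
    """Maximum-likelihood fit: point estimates, covariance and Wald table."""

    model: WeibullPHModel
    covariance: pd.DataFrame
    loglik: float
    converged: bool
    n_used: int
    events_used: int
    wald: pd.DataFrame
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_used": self.n_used,
            "events_used": self.events_used,
            "wald": self.wald.reset_index().to_dict(orient="records"),
            "covariance": self.covariance.values.tolist(),
            "parameter_order": list(self.covariance.columns),
        }


def _profile_value(profile, name: str) -> float:
    if isinstance(profile, RiskFactorProfile):
        v = getattr(profile, name)
    else:
        v = profile.get(name)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise KeyError(f"profile is missing covariate {name!r}")
    return float(v)


def linear_predictor(model: WeibullPHModel, profile) -> float:
    """beta @ x over the model's covariates (no age term; age is the timescale)."""
    return float(sum(b * _profile_value(profile, k) for k, b in model.beta.items()))


def cumulative_baseline_hazard(alpha: float, shape: float, t) -> float | np.ndarray:
    """H0(t) = exp(alpha) * t**shape, evaluated in log space for stability."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    if not shape > 0:
        raise ValueError("shape must be positive")
    out = np.exp(alpha + shape * np.log(t))
    return float(out) if out.ndim == 0 else out


def predict_absolute_risk(model: WeibullPHModel, profile, horizon: float) -> float:
    """Probability of the event within ``horizon`` years given event-free
    survival to the profile's age; strictly in [0, 1)."""
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    a0 = _profile_value(profile, "age")
    if a0 < 16:
        raise ValueError("baseline age below study inclusion (16)")
    sex = profile.sex if isinstance(profile, RiskFactorProfile) else profile["sex"]
    if sex not in model.alpha:
        raise KeyError(f"model has no stratum {sex!r}")
    a, p = model.alpha[sex], model.shape[sex]
    dh = cumulative_baseline_hazard(a, p, a0 + horizon) - cumulative_baseline_hazard(a, p, a0)
    lp = linear_predictor(model, profile)
    return float(-np.expm1(-dh * np.exp(lp)))


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Two-sided Wald z-test: z = estimate/se, p = 2(1 - Phi(|z|))."""
    if not se > 0:
        raise ValueError("se must be positive")
    z = estimate / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        if c not in df.columns:
            raise KeyError(f"covariate {c!r} not in table")
        col = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(
                f"covariate {c!r} has missing values; run exclude_missing first"
            )
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _arrays(table: CohortTable, covariates: Sequence[str]):
    df = table.df
    t0 = pd.to_numeric(df["entry_age"]).to_numpy(dtype=float)
    t1 = pd.to_numeric(df["exit_age"]).to_numpy(dtype=float)
    d = df["event"].astype(bool).to_numpy()
    strata = df["sex"].astype(str).to_numpy()
    X = _design(df, covariates)
    if np.any(t0 <= 0) or np.any(t1 <= t0):
        raise ValueError("require 0 < entry_age < exit_age for every record")
    return t0, t1, d, strata, X


def _unpack(params: np.ndarray, n_cov: int, n_strata: int = 2):
    alpha = params[0:n_strata]
    logp = params[n_strata:2 * n_strata]
    beta = params[2 * n_strata:2 * n_strata + n_cov]
    return alpha, logp, beta


def _loglik_terms(params, t0, t1, d, s_idx, X, n_strata: int = 2):
    """Per-subject log-likelihood on the working scale (alpha, log p, beta)."""
    n_cov = X.shape[1]
    alpha, logp, beta = _unpack(np.asarray(params, dtype=float), n_cov, n_strata)
    p = np.exp(logp)
    a_i, p_i = alpha[s_idx], p[s_idx]
    lp = X @ beta if n_cov else np.zeros(len(t0))
    lt0, lt1 = np.log(t0), np.log(t1)
    # dH = exp(a + p*log t1) * (1 - exp(-p*(log t1 - log t0))), stable for t1 ~ t0
    log_h1 = a_i + p_i * lt1
    dH = np.exp(log_h1) * (-np.expm1(-p_i * (lt1 - lt0)))
    ll = -np.exp(lp) * dH
    ll[d] += a_i[d] + np.log(p_i[d]) + (p_i[d] - 1.0) * lt1[d] + lp[d]
    return ll


def log_likelihood(params, table: CohortTable, covariates: Sequence[str]) -> float:
    """Left-truncated Weibull-PH log likelihood, additive over subjects.

    ``params`` is the flat working vector
    ``(alpha_male, alpha_female, log p_male, log p_female, beta...)``.
    Returns ``-inf`` (with a log record) for non-finite parameter values.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        logger.debug("log_likelihood: non-finite parameters, returning -inf")
        return -np.inf
    t0, t1, d, strata, X = _arrays(table, covariates)
    s_idx = np.array([SEX_LABELS.index(s) for s in strata])
    return float(np.sum(_loglik_terms(params, t0, t1, d, s_idx, X)))


def _nll_and_grad(params, t0, t1, d, s_idx, X, lt0, lt1, n_strata=2):
    n_cov = X.shape[1]
    alpha, logp, beta = _unpack(params, n_cov, n_strata)
    p = np.exp(logp)
    a_i, p_i = alpha[s_idx], p[s_idx]
    lp = X @ beta if n_cov else np.zeros(len(t0))
    # line searches can probe parameters where exp() overflows; report a huge
    # finite objective there so the optimizer backtracks
    if np.max(a_i + p_i * lt1 + lp) > 500.0:
        return 1e15, np.zeros(2 * n_strata + n_cov)
    elp = np.exp(lp)
    h1 = np.exp(a_i + p_i * lt1)          # H0 at exit
    h0 = np.exp(a_i + p_i * lt0)          # H0 at entry
    dH = h1 * (-np.expm1(-p_i * (lt1 - lt0)))
    ll = -elp * dH
    ll[d] += a_i[d] + np.log(p_i[d]) + (p_i[d] - 1.0) * lt1[d] + lp[d]

    # gradient pieces
    resid = d.astype(float) - elp * dH    # d ll / d alpha_s and per-covariate factor
    dH_dp = h1 * lt1 - h0 * lt0           # d dH / d p
    dll_dp = -elp * dH_dp
    dll_dp[d] += 1.0 / p_i[d] + lt1[d]

    grad = np.zeros(2 * n_strata + n_cov)
    for s in range(n_strata):
        m = s_idx == s
        grad[s] = resid[m].sum()
        grad[n_strata + s] = (dll_dp[m] * p_i[m]).sum()   # chain rule through log p
    if n_cov:
        grad[2 * n_strata:] = X.T @ resid
    return -ll.sum(), -grad


def _start_values(t0, t1, d, s_idx, n_cov, n_strata=2, p0=5.0):
    """alpha from a stratum moment match at fixed shape p0, beta = 0."""
    params = np.zeros(2 * n_strata + n_cov)
    for s in range(n_strata):
        m = s_idx == s
        if m.sum() == 0:
            continue
        denom = np.sum(t1[m] ** p0 - t0[m] ** p0)
        ev = max(d[m].sum(), 0.5)
        params[s] = np.log(ev / max(denom, 1e-300))
        params[n_strata + s] = np.log(p0)
    return params


def _natural_nll(theta, t0, t1, d, s_idx, X, lt0, lt1, n_strata=2):
    """NLL as a function of (alpha..., p..., beta) on the natural scale."""
    work = theta.copy()
    work[n_strata:2 * n_strata] = np.log(theta[n_strata:2 * n_strata])
    nll, _ = _nll_and_grad(work, t0, t1, d, s_idx, X, lt0, lt1, n_strata)
    return nll


def fit_weibull_ph(
    table: CohortTable,
    covariates: Sequence[str],
    options: Mapping | None = None,
) -> FitResult:
    """Maximize the left-truncated likelihood over (alpha_s, log p_s, beta).

    Quasi-Newton (L-BFGS-B) with analytic gradients; the covariance matrix is
    the inverse of the numerically differentiated observed information on the
    natural scale (alpha, p, beta), so Wald intervals for the shapes are on
    the shape scale.  A stratum without events is flagged in ``message`` and
    the fit is marked non-converged rather than silently reported.
    """
    opts = {"gtol": 1e-8, "maxiter": 500, "p0": 5.0}
    opts.update(options or {})
    covariates = list(covariates)
    t0, t1, d, strata, X = _arrays(table, covariates)
    labels = [s for s in SEX_LABELS if (strata == s).any()]
    if not labels:
        raise ValueError("no recognised sex strata in table")
    ns = len(labels)
    s_idx = np.array([labels.index(s) for s in strata])
    lt0, lt1 = np.log(t0), np.log(t1)
    n_cov = len(covariates)

    flags = []
    dead_strata = [lab for s, lab in enumerate(labels) if d[s_idx == s].sum() == 0]
    if dead_strata:
        # a stratum without events has no identified baseline (alpha -> -inf);
        # drop it from the fit rather than let the optimizer diverge
        flags.append(f"stratum(s) {dead_strata} have no events; excluded from fit")
        keep = ~np.isin(strata, dead_strata)
        t0, t1, d, strata, X = t0[keep], t1[keep], d[keep], strata[keep], X[keep]
        labels = [lab for lab in labels if lab not in dead_strata]
        if not labels:
            raise ValueError("no stratum has any events; model unidentifiable")
        ns = len(labels)
        s_idx = np.array([labels.index(s) for s in strata])
        lt0, lt1 = np.log(t0), np.log(t1)

    x0 = _start_values(t0, t1, d, s_idx, n_cov, n_strata=ns, p0=opts["p0"])
    res = optimize.minimize(
        _nll_and_grad, x0, args=(t0, t1, d, s_idx, X, lt0, lt1, ns),
        jac=True, method="L-BFGS-B",
        options={"maxiter": opts["maxiter"], "gtol": opts["gtol"], "ftol": 1e-12},
    )
    converged = bool(res.success) and not flags
    if not res.success:
        flags.append(f"optimizer: {res.message}")
        logger.warning("fit_weibull_ph did not converge: %s", res.message)

    alpha, logp, beta = _unpack(res.x, n_cov, ns)
    p = np.exp(logp)
    model = WeibullPHModel(
        alpha={lab: float(a) for lab, a in zip(labels, alpha)},
        shape={lab: float(v) for lab, v in zip(labels, p)},
        beta={c: float(b) for c, b in zip(covariates, beta)},
    )

    names = ([f"alpha_{lab}" for lab in labels] + [f"shape_{lab}" for lab in labels]
             + covariates)
    theta = np.concatenate([alpha, p, beta])
    try:
        H = approx_hess(theta, _natural_nll, args=(t0, t1, d, s_idx, X, lt0, lt1, ns))
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((len(theta), len(theta)), np.nan)
        flags.append("observed information singular; covariance unavailable")
        converged = False
    cov_df = pd.DataFrame(cov, index=names, columns=names)

    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    rows = []
    for name, est, s_e in zip(names, theta, se):
        if np.isfinite(s_e) and s_e > 0:
            z, pval = wald_test(est, s_e)
        else:
            z, pval = np.nan, np.nan
        rows.append({"parameter": name, "estimate": est, "se": s_e, "z": z,
                     "p": pval, "ci_low": est - 1.959963984540054 * s_e,
                     "ci_high": est + 1.959963984540054 * s_e})
    wald = pd.DataFrame(rows).set_index("parameter")

    return FitResult(
        model=model, covariance=cov_df, loglik=float(-res.fun),
        converged=converged, n_used=len(t0), events_used=int(d.sum()),
        wald=wald, message="; ".join(flags),
    )
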