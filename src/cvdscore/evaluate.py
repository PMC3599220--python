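"""Censoring-aware comparison of risk prediction models.

All metrics are computed at a fixed horizon on the follow-up timescale:
each subject is an *event* (CVD death within the horizon of entry), *event
free* (still under observation at entry + horizon), or *censored before the
horizon*.  Censoring is handled by inverse-probability-of-censoring weighting
(IPCW): weights come from the Kaplan-Meier estimate G of the censoring
distribution, events weighted 1/G(T-), event-free subjects 1/G(horizon),
censored-before-horizon subjects 0.

Provided: IPCW Brier score with leave-one-out (or k-fold) cross-validation,
IPCW cumulative/dynamic AUC at the horizon, discrimination slopes and the
integrated discrimination improvement (IDI) with a paired Wald test, a paired
permutation test for Brier-score differences, and an external-validation
driver that scores a new cohort with frozen coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import CohortTable
from .weibull import FitResult, WeibullPHModel, fit_weibull_ph, wald_test

logger = logging.getLogger(__name__)

EVENT, EVENT_FREE, CENSORED = "event", "event_free", "censored_before_horizon"


@dataclass
class PredictionSet:
    """Per-subject predicted risks at a horizon, aligned with a CohortTable."""

    risks: np.ndarray
    horizon: float
    model_id: str = ""

    def __post_init__(self) -> None:
        self.risks = np.asarray(self.risks, dtype=float)
        if np.any((self.risks < 0) | (self.risks > 1)):
            raise ValueError("risks must lie in [0, 1]")


@dataclass
class EvalResult:
    """Comparison of two prediction models on one cohort."""

    horizon: float
    n: int
    events_at_horizon: int
    brier: dict[str, float]
    auc: dict[str, float]
    slope: dict[str, float]
    idi: float
    idi_se: float
    idi_wald_p: float
    perm_p: float
    brier_cv: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon, "n": self.n,
            "events_at_horizon": self.events_at_horizon,
            "brier": self.brier, "brier_cv": self.brier_cv, "auc": self.auc,
            "slope": self.slope, "idi": self.idi, "idi_se": self.idi_se,
            "idi_wald_p": self.idi_wald_p, "perm_p": self.perm_p,
            "notes": self.notes,
        }


def predict_risks(model: WeibullPHModel, table: CohortTable, horizon: float,
                  model_id: str = "") -> PredictionSet:
    """Score every subject of a cohort with a fitted (or published) model."""
    df = table.df
    sex = df["sex"].astype(str).to_numpy()
    a0 = pd.to_numeric(df["entry_age"]).to_numpy(dtype=float)
    for c in model.beta:
        if pd.to_numeric(df[c], errors="coerce").isna().any():
            raise KeyError(f"covariate {c!r} missing in table; cannot score")
    alpha = np.array([model.alpha[s] for s in sex])
    p = np.array([model.shape[s] for s in sex])
    lp = np.zeros(len(df))
    for name, b in model.beta.items():
        lp += b * pd.to_numeric(df[name]).to_numpy(dtype=float)
    dh = np.exp(alpha + p * np.log(a0 + horizon)) - np.exp(alpha + p * np.log(a0))
    risks = -np.expm1(-dh * np.exp(lp))
    return PredictionSet(risks=risks, horizon=horizon, model_id=model_id)


def _follow_up(table: CohortTable):
    df = table.df
    t = (pd.to_numeric(df["exit_age"]) - pd.to_numeric(df["entry_age"])).to_numpy(dtype=float)
    d = df["event"].astype(bool).to_numpy()
    return t, d


def status_at_horizon(table: CohortTable, horizon: float) -> np.ndarray:
    """Per-subject status at entry + horizon (vectorized over the table)."""
    t, d = _follow_up(table)
    out = np.full(len(t), EVENT_FREE, dtype=object)
    out[(t <= horizon) & d] = EVENT
    out[(t < horizon) & ~d] = CENSORED
    return out


def ipcw_weights(table: CohortTable, horizon: float) -> np.ndarray:
    """Inverse-probability-of-censoring weights at the horizon.

    G is the Kaplan-Meier estimate of the censoring survival function on the
    follow-up timescale (censorings are the "events" of G).  Events before
    the horizon get 1/G(T-), subjects event-free at the horizon 1/G(horizon),
    censored-before-horizon subjects 0.  Raises if G vanishes at a time where
    a weight is needed.
    """
    t, d = _follow_up(table)
    status = status_at_horizon(table, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=~d)  # censoring distribution
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)

    def G_left(x):
        # left limit G(x-): survival just before x
        idx = np.searchsorted(times, x, side="left") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])

    def G_at(x):
        idx = np.searchsorted(times, x, side="right") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])

    w = np.zeros(len(t))
    ev = status == EVENT
    free = status == EVENT_FREE
    g_ev = G_left(t[ev])
    g_h = G_at(np.full(free.sum(), horizon))
    for label, g, where in (("event", g_ev, t[ev]), ("horizon", g_h, np.full(free.sum(), horizon))):
        if np.any(g <= 0):
            bad = where[np.asarray(g) <= 0]
            raise ValueError(f"censoring survival G is 0 at needed {label} time(s) {bad[:3]}")
    w[ev] = 1.0 / g_ev
    w[free] = 1.0 / g_h
    return w


def brier_score(preds: PredictionSet, table: CohortTable, horizon: float | None = None) -> float:
    """IPCW mean squared error between predicted risk and the horizon outcome.

    With no censoring before the horizon this reduces exactly to the plain
    mean squared difference.
    """
    horizon = preds.horizon if horizon is None else horizon
    if len(preds.risks) != len(table):
        raise ValueError("prediction set not aligned with table")
    status = status_at_horizon(table, horizon)
    w = ipcw_weights(table, horizon)
    y = (status == EVENT).astype(float)
    return float(np.sum(w * (y - preds.risks) ** 2) / len(table))


def auc_at_horizon(preds: PredictionSet, table: CohortTable,
                   horizon: float | None = None, ipcw: bool = True) -> float:
    """IPCW cumulative/dynamic AUC at the horizon.

    Probability that a subject with an event by the horizon is assigned a
    higher risk than one event-free at the horizon; risk ties count 1/2.
    ``ipcw=False`` gives the unweighted binary-outcome AUC over subjects with
    known horizon status (sensitivity option).
    """
    horizon = preds.horizon if horizon is None else horizon
    status = status_at_horizon(table, horizon)
    ev, free = status == EVENT, status == EVENT_FREE
    if ev.sum() == 0 or free.sum() == 0:
        raise ValueError("AUC undefined: need at least one event and one event-free subject")
    if ipcw:
        w = ipcw_weights(table, horizon)
        w_ev, w_free = w[ev], w[free]
    else:
        w_ev, w_free = np.ones(ev.sum()), np.ones(free.sum())
    r_ev, r_free = preds.risks[ev], preds.risks[free]
    # pairwise comparison, vectorized (cohorts here are small enough)
    diff = r_ev[:, None] - r_free[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    wmat = w_ev[:, None] * w_free[None, :]
    return float(np.sum(wmat * conc) / np.sum(wmat))


def discrimination_slope(preds: PredictionSet, table: CohortTable,
                         horizon: float | None = None) -> float:
    """Mean predicted risk among horizon events minus mean among event-free
    subjects; censored-before-horizon subjects are excluded."""
    horizon = preds.horizon if horizon is None else horizon
    status = status_at_horizon(table, horizon)
    ev, free = status == EVENT, status == EVENT_FREE
    if ev.sum() == 0 or free.sum() == 0:
        raise ValueError("slope undefined: need events and event-free subjects")
    return float(preds.risks[ev].mean() - preds.risks[free].mean())


def idi(preds_new: PredictionSet, preds_old: PredictionSet, table: CohortTable,
        horizon: float | None = None) -> tuple[float, float, float]:
    """Integrated discrimination improvement with a paired Wald test.

    IDI = slope(new) - slope(old).  The standard error uses the paired
    per-subject risk differences d_i = r_new,i - r_old,i:
    se = sqrt(var(d | events)/n_ev + var(d | event-free)/n_free).
    Returns (idi, se, two-sided Wald p); p = 1 when both models give
    identical predictions.
    """
    horizon = preds_new.horizon if horizon is None else horizon
    if len(preds_new.risks) != len(preds_old.risks) or len(preds_new.risks) != len(table):
        raise ValueError("prediction sets not aligned")
    status = status_at_horizon(table, horizon)
    ev, free = status == EVENT, status == EVENT_FREE
    if ev.sum() == 0:
        raise ValueError("IDI undefined without events")
    d = preds_new.risks - preds_old.risks
    value = float(d[ev].mean() - d[free].mean())
    var = 0.0
    if ev.sum() > 1:
        var += d[ev].var(ddof=1) / ev.sum()
    if free.sum() > 1:
        var += d[free].var(ddof=1) / free.sum()
    se = float(np.sqrt(var))
    if se == 0.0:
        return value, 0.0, 1.0 if value == 0.0 else 0.0
    z, p = wald_test(value, se)
    return value, se, p


def permutation_test_brier(preds_a: PredictionSet, preds_b: PredictionSet,
                           table: CohortTable, horizon: float | None = None,
                           n_perm: int = 1999, seed: int = 0) -> float:
    """Paired permutation test for |Brier(a) - Brier(b)|.

    Under the null that the two models predict equally well, each subject's
    pair of risks is exchangeable; null draws swap each pair independently
    with probability 1/2.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    horizon = preds_a.horizon if horizon is None else horizon
    status = status_at_horizon(table, horizon)
    w = ipcw_weights(table, horizon)
    y = (status == EVENT).astype(float)
    n = len(table)
    ra, rb = preds_a.risks, preds_b.risks
    sq_a, sq_b = w * (y - ra) ** 2, w * (y - rb) ** 2
    observed = abs(sq_a.mean() - sq_b.mean())
    rng = np.random.default_rng(seed)
    # swapping risks swaps the per-subject squared-error contributions
    swap = rng.random((n_perm, n)) < 0.5
    delta = sq_a - sq_b
    null = np.abs((np.where(swap, -delta, delta)).mean(axis=1))
    return float((1 + np.sum(null >= observed - 1e-15)) / (n_perm + 1))


CVMode = Literal["exact", "kfold"]


def cross_validated_risks(table: CohortTable, covariates: Sequence[str],
                          horizon: float, mode: CVMode = "kfold", k: int = 10,
                          seed: int = 0) -> PredictionSet:
    """Out-of-fold predicted risks: exact leave-one-out refits, or k-fold.

    Any non-convergent refit is logged and its fold's subjects are scored by
    the full-sample fit (flagged in the model_id) rather than dropped.
    """
    n = len(table)
    risks = np.empty(n)
    full = fit_weibull_ph(table, covariates)
    flagged = []
    if mode == "exact":
        folds = [[i] for i in range(n)]
    elif mode == "kfold":
        idx = np.random.default_rng(seed).permutation(n)
        folds = [sorted(f.tolist()) for f in np.array_split(idx, k)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        train = CohortTable(df=table.df[mask].reset_index(drop=True),
                            provenance=table.provenance)
        fit = fit_weibull_ph(train, covariates)
        use = fit.model if fit.converged else full.model
        if not fit.converged:
            flagged.extend(fold)
        held = CohortTable(df=table.df.iloc[fold].reset_index(drop=True),
                           provenance=table.provenance)
        risks[fold] = predict_risks(use, held, horizon).risks
    if flagged:
        logger.warning("cross_validated_risks: %d subjects scored by the "
                       "full-sample fit after non-convergent refits", len(flagged))
    tag = f"cv-{mode}" + (":partial" if flagged else "")
    return PredictionSet(risks=risks, horizon=horizon, model_id=tag)


def loocv_brier(table: CohortTable, covariates: Sequence[str], horizon: float,
                mode: CVMode = "exact", k: int = 10, seed: int = 0) -> float:
    """Cross-validated (leave-one-out by default) IPCW mean Brier score."""
    preds = cross_validated_risks(table, covariates, horizon, mode=mode, k=k, seed=seed)
    return brier_score(preds, table, horizon)


def compare_models(table: CohortTable, covariates_a: Sequence[str],
                   covariates_b: Sequence[str], horizon: float = 10.0,
                   cv: CVMode | None = "kfold", k: int = 10,
                   n_perm: int = 1999, seed: int = 0) -> EvalResult:
    """Fit two covariate specifications on the same cohort and compare them.

    Reported Brier and AUC use cross-validated predictions when ``cv`` is
    given (k-fold by default, ``"exact"`` for true leave-one-out); the IDI
    and permutation test compare the same prediction sets.
    """
    if cv is None:
        pa = predict_risks(fit_weibull_ph(table, covariates_a).model, table, horizon, "a")
        pb = predict_risks(fit_weibull_ph(table, covariates_b).model, table, horizon, "b")
    else:
        pa = cross_validated_risks(table, covariates_a, horizon, mode=cv, k=k, seed=seed)
        pb = cross_validated_risks(table, covariates_b, horizon, mode=cv, k=k, seed=seed + 1)
    res = _evaluate_pair(pa, pb, table, horizon, n_perm, seed,
                         labels=("+".join(covariates_a), "+".join(covariates_b)))
    if cv is not None:
        res.brier_cv = dict(res.brier)
        res.notes = f"Brier/AUC computed on {cv} cross-validated predictions"
    return res


def external_validate(fit: FitResult | WeibullPHModel,
                      table: CohortTable,
                      comparison_fit: FitResult | WeibullPHModel,
                      horizon: float = 10.0, n_perm: int = 1999,
                      seed: int = 0) -> EvalResult:
    """Score an external cohort with frozen coefficients — no refitting.

    Both models' risks come straight from the supplied estimates; Brier
    (non-cross-validated), AUC, IDI and the permutation p-value are computed
    on the external table.
    """
    model_a = fit.model if isinstance(fit, FitResult) else fit
    model_b = comparison_fit.model if isinstance(comparison_fit, FitResult) else comparison_fit
    pa = predict_risks(model_a, table, horizon, "external:a")
    pb = predict_risks(model_b, table, horizon, "external:b")
    res = _evaluate_pair(pa, pb, table, horizon, n_perm, seed,
                         labels=("+".join(model_a.beta), "+".join(model_b.beta)))
    res.notes = "external validation: frozen coefficients, apparent Brier"
    return res


def _evaluate_pair(pa: PredictionSet, pb: PredictionSet, table: CohortTable,
                   horizon: float, n_perm: int, seed: int,
                   labels: tuple[str, str]) -> EvalResult:
    la, lb = labels
    if la == lb:
        la, lb = la + ":a", lb + ":b"
    status = status_at_horizon(table, horizon)
    value, se, p_wald = idi(pa, pb, table, horizon)
    return EvalResult(
        horizon=horizon, n=len(table),
        events_at_horizon=int((status == EVENT).sum()),
        brier={la: brier_score(pa, table, horizon), lb: brier_score(pb, table, horizon)},
        auc={la: auc_at_horizon(pa, table, horizon), lb: auc_at_horizon(pb, table, horizon)},
        slope={la: discrimination_slope(pa, table, horizon),
               lb: discrimination_slope(pb, table, horizon)},
        idi=value, idi_se=se, idi_wald_p=p_wald,
        perm_p=permutation_test_brier(pa, pb, table, horizon, n_perm=n_perm, seed=seed),
    )
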