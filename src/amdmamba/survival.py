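"""Cox partial likelihood and the survival evaluation suite.

The training objective is the negative Cox partial log-likelihood

    L(beta) = - sum_{i: delta_i = 1} [ beta_i - log sum_{j in R(t_i)} exp(beta_j) ]

with risk set R(t) = {j : t_j >= t} (a subject is at risk at its own event
time) and the Breslow convention for tied event times — the formula above
is exactly Breslow under ties; Efron's correction is available behind a
flag.  Evaluation covers Harrell's concordance index, the cumulative/
dynamic time-dependent AUC with inverse-probability-of-censoring weights,
training-median risk dichotomization (the derived low/high biomarker),
Kaplan-Meier curves with a two-group log-rank test, and univariate /
multivariate Cox screening (delegated to lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Tensor

__all__ = [
    "SurvivalRecord",
    "cox_loss",
    "cox_loss_tensor",
    "concordance_index",
    "time_dependent_auc",
    "dichotomize_biomarker",
    "km_curves",
    "cox_screen",
]


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float
    event: int
    risk: float


def _validate(time, event, risk=None):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")
    event = event.astype(int)
    if risk is not None:
        risk = np.asarray(risk, dtype=float)
        if np.any(~np.isfinite(risk)):
            raise ValueError("risks must be finite")
        return time, event, risk
    return time, event


def cox_loss(time, event, risk, ties: str = "breslow", reduction: str = "sum") -> float:
    """Negative Cox partial log-likelihood of the given log-risks."""
    time, event, risk = _validate(time, event, risk)
    if event.sum() == 0:
        raise ValueError("Cox partial likelihood undefined with zero events")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    m = risk.max()
    exp_r = np.exp(risk - m)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        tied = (time == t) & (event == 1)
        d = int(tied.sum())
        denom = exp_r[at_risk].sum()
        if ties == "breslow" or d == 1:
            ll += (risk[tied] - m).sum() - d * np.log(denom)
        else:
            tied_sum = exp_r[tied].sum()
            ll += (risk[tied] - m).sum() - sum(
                np.log(denom - (k / d) * tied_sum) for k in range(d)
            )
    loss = -ll
    if reduction == "mean":
        loss /= event.sum()
    return float(loss)


def cox_loss_tensor(beta: Tensor, time, event, reduction: str = "mean") -> Tensor:
    """Differentiable Breslow negative partial log-likelihood for training."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("Cox partial likelihood undefined with zero events")
    n = time.shape[0]
    # at_risk[i, j] = 1 if t_j >= t_i ; rows restricted to events below
    at_risk = (time[None, :] >= time[:, None]).astype(float)
    ev_idx = np.flatnonzero(event == 1)
    mask = Tensor(at_risk[ev_idx])  # (E, n) constants
    shift = Tensor(np.full((len(ev_idx), 1), float(beta.data.max())))
    z = (beta.reshape(1, n) - shift).exp()  # (E, n) broadcast rows
    log_den = (z * mask).sum(axis=-1, keepdims=True).log() + shift  # (E,1)
    beta_ev = beta[ev_idx].reshape(len(ev_idx), 1)
    loss = (log_den - beta_ev).sum()
    if reduction == "mean":
        loss = loss * (1.0 / len(ev_idx))
    return loss.reshape(())


def concordance_index(time, event, risk) -> float:
    """Harrell's C over comparable pairs (t_i < t_j, delta_i = 1).

    Higher risk should go with earlier events; tied risks count 1/2.
    Invariant under strictly monotone transforms of the risk score.
    """
    time, event, risk = _validate(time, event, risk)
    earlier = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_pairs = earlier.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    higher = risk[:, None] > risk[None, :]
    ties = risk[:, None] == risk[None, :]
    concordant = (earlier & higher).sum() + 0.5 * (earlier & ties).sum()
    return float(concordant / n_pairs)


def _censoring_km_left(time, event):
    """Kaplan-Meier of the censoring distribution, G(t-), evaluated at the
    subject's own time (left limit)."""
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    c_sorted = 1 - event[order]  # censoring 'events'
    n = len(time)
    uniq = np.unique(t_sorted)
    surv = 1.0
    g_at = {}  # G evaluated just before each unique time
    for t in uniq:
        g_at[t] = surv
        at_risk = (t_sorted >= t).sum()
        d_cens = ((t_sorted == t) & (c_sorted == 1)).sum()
        if at_risk > 0:
            surv *= 1.0 - d_cens / at_risk
    return np.array([g_at[t] for t in time])


def time_dependent_auc(time, event, risk, horizon: float) -> float:
    """Cumulative/dynamic AUC at `horizon` with IPCW case weights.

    Cases: events by the horizon; controls: still event-free past it.
    Case i is weighted by 1/G(t_i-), where G is the Kaplan-Meier estimate
    of the censoring survival function. With no censoring before the
    horizon this reduces to the plain rank-sum AUC of the risk score.
    """
    time, event, risk = _validate(time, event, risk)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("need at least one case and one control at the horizon")
    g_left = _censoring_km_left(time, event)
    w = np.zeros_like(time)
    w[cases] = 1.0 / g_left[cases]
    num = 0.0
    r_cases = risk[cases]
    w_cases = w[cases]
    r_ctrl = risk[controls]
    gt = (r_cases[:, None] > r_ctrl[None, :]).astype(float)
    eq = (r_cases[:, None] == r_ctrl[None, :]).astype(float)
    num = (w_cases[:, None] * (gt + 0.5 * eq)).sum()
    den = w_cases.sum() * controls.sum()
    return float(num / den)


def dichotomize_biomarker(train_risk, apply_risk, threshold: float | None = None):
    """Split risks into low/high at the training-median threshold.

    Returns (groups, threshold) where groups is an array of 'low'/'high';
    values exactly at the threshold are assigned to 'low'.
    """
    train_risk = np.asarray(train_risk, dtype=float)
    apply_risk = np.asarray(apply_risk, dtype=float)
    if threshold is None:
        if np.ptp(train_risk) == 0:
            warnings.warn("constant training risks; all samples assigned low-risk")
            threshold = float(train_risk[0])
        else:
            threshold = float(np.median(train_risk))
    groups = np.where(apply_risk > threshold, "high", "low")
    return groups, threshold


def km_curves(time, event, groups):
    """Kaplan-Meier curve per risk group plus the two-group log-rank test.

    Returns (curves, stat, p) where curves maps group name to a DataFrame
    with columns (time, survival).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time, event = _validate(time, event)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if any((groups == g).sum() == 0 for g in names) or len(names) == 0:
        raise ValueError("each risk group must be non-empty")
    curves = {}
    for g in names:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(time, groups, event)
    return curves, float(res.test_statistic), float(res.p_value)


def _collinear_columns(X: pd.DataFrame) -> list:
    """Name columns involved in exact linear dependence via QR."""
    arr = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr - arr.mean(axis=0))
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    return [c for c, b in zip(X.columns, bad) if b]


def cox_screen(
    table: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list | None = None,
    mode: str = "univariate",
    alpha_select: float = 0.05,
) -> pd.DataFrame:
    """Univariate or multivariate Cox proportional-hazards screening.

    Univariate mode fits one model per covariate; multivariate mode first
    selects covariates with univariate Wald p < `alpha_select`, then fits
    a joint model.  Returns a table of hazard ratios, 95% CIs and p-values.
    """
    from lifelines import CoxPHFitter

    if covariates is None:
        covariates = [c for c in table.columns if c not in (duration_col, event_col)]
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")

    def _fit(cols):
        X = table[cols]
        bad = _collinear_columns(X)
        if len(cols) > 1 and bad:
            raise np.linalg.LinAlgError(
                f"singular design matrix; collinear columns: {bad}"
            )
        cph = CoxPHFitter()
        cph.fit(table[cols + [duration_col, event_col]],
                duration_col=duration_col, event_col=event_col)
        s = cph.summary
        return pd.DataFrame(
            {
                "covariate": s.index,
                "coef": s["coef"].to_numpy(),
                "HR": s["exp(coef)"].to_numpy(),
                "CI_lower": s["exp(coef) lower 95%"].to_numpy(),
                "CI_upper": s["exp(coef) upper 95%"].to_numpy(),
                "p": s["p"].to_numpy(),
            }
        ).reset_index(drop=True)

    if mode == "univariate":
        rows = [_fit([c]) for c in covariates]
        return pd.concat(rows, ignore_index=True)

    uni = pd.concat([_fit([c]) for c in covariates], ignore_index=True)
    selected = uni.loc[uni["p"] < alpha_select, "covariate"].tolist()
    if not selected:
        raise ValueError("no covariate passed univariate selection")
    return _fit(selected)
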