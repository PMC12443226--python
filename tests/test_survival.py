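"""Cox loss, concordance, time-dependent AUC, KM/log-rank, Cox screening."""

import numpy as np
import pandas as pd
import pytest

from amdmamba.nn import Tensor
from amdmamba.survival import (
    concordance_index,
    cox_loss,
    cox_loss_tensor,
    dichotomize_biomarker,
    km_curves,
    cox_screen,
    time_dependent_auc,
)


# ------------------------------------------------------------- oracle helpers
def cox_oracle(time, event, risk):
    """Brute-force double loop over events and risk sets."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            denom = sum(np.exp(risk[j]) for j in range(len(time)) if time[j] >= time[i])
            ll += risk[i] - np.log(denom)
    return -ll


def cindex_oracle(time, event, risk):
    num = den = 0.0
    for i in range(len(time)):
        for j in range(len(time)):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


# ------------------------------------------------------------------ cox loss
def test_singleton_event_has_zero_loss():
    assert cox_loss([3.0], [1], [1.7]) == pytest.approx(0.0)


def test_two_subject_hand_computation():
    # events at t=1 (risk set both) and t=2 (risk set itself): loss = log 2
    assert cox_loss([1.0, 2.0], [1, 1], [0.0, 0.0]) == pytest.approx(np.log(2.0))


def test_matches_bruteforce_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(2, 9)
        time = rng.exponential(5.0, n).round(1) + 0.1  # allow ties
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        risk = rng.normal(0, 1.5, n)
        assert cox_loss(time, event, risk) == pytest.approx(
            cox_oracle(time, event, risk), abs=1e-6
        )


def test_shift_invariance_in_log_risk():
    rng = np.random.default_rng(1)
    time, event, risk = rng.exponential(5, 8), rng.integers(0, 2, 8), rng.normal(size=8)
    event[0] = 1
    a = cox_loss(time + 0.1, event, risk)
    b = cox_loss(time + 0.1, event, risk + 123.456)
    assert a == pytest.approx(b, abs=1e-8)


def test_zero_events_raise():
    with pytest.raises(ValueError, match="zero events"):
        cox_loss([1.0, 2.0], [0, 0], [0.0, 0.0])


def test_efron_equals_breslow_without_ties_and_runs_with_ties():
    rng = np.random.default_rng(2)
    time = np.arange(1.0, 7.0)
    event = np.array([1, 0, 1, 1, 0, 1])
    risk = rng.normal(size=6)
    assert cox_loss(time, event, risk, ties="efron") == pytest.approx(
        cox_loss(time, event, risk, ties="breslow")
    )
    tied_t = np.array([1.0, 1.0, 2.0, 3.0])
    ev = np.array([1, 1, 1, 0])
    assert np.isfinite(cox_loss(tied_t, ev, risk[:4], ties="efron"))


def test_tensor_loss_agrees_with_numpy_and_is_differentiable():
    rng = np.random.default_rng(3)
    time = rng.exponential(5, 10) + 0.1
    event = rng.integers(0, 2, 10)
    event[:2] = 1
    beta = Tensor(rng.normal(size=10), requires_grad=True)
    loss = cox_loss_tensor(beta, time, event, reduction="sum")
    assert loss.item() == pytest.approx(cox_loss(time, event, beta.data), abs=1e-8)
    loss.backward()
    # gradient check on one coordinate
    eps = 1e-6
    bumped = beta.data.copy()
    bumped[4] += eps
    num = (cox_loss(time, event, bumped) - cox_loss(time, event, beta.data)) / eps
    assert beta.grad[4] == pytest.approx(num, abs=1e-4)


# ---------------------------------------------------------------- concordance
def test_perfectly_anti_ordered_risks_give_one():
    time = np.arange(1.0, 9.0)
    risk = -time
    assert concordance_index(time, np.ones(8, int), risk) == 1.0


def test_fixed_instance_equals_exhaustive_enumeration():
    rng = np.random.default_rng(4)
    time = rng.exponential(5, 8).round(1) + 0.1
    event = np.array([1, 0, 1, 1, 0, 1, 1, 0])
    risk = rng.normal(size=8).round(1)  # rounding provokes ties
    assert concordance_index(time, event, risk) == pytest.approx(
        cindex_oracle(time, event, risk)
    )


def test_invariance_under_monotone_transform():
    rng = np.random.default_rng(5)
    time = rng.exponential(5, 30) + 0.1
    event = rng.integers(0, 2, 30)
    event[0] = 1
    risk = rng.normal(size=30)
    base = concordance_index(time, event, risk)
    assert concordance_index(time, event, np.exp(risk)) == pytest.approx(base)
    assert concordance_index(time, event, 3 * risk - 7) == pytest.approx(base)


def test_agrees_with_lifelines_on_continuous_times():
    from lifelines.utils import concordance_index as ll_cindex

    rng = np.random.default_rng(6)
    time = rng.exponential(5, 60) + rng.uniform(0, 1e-6, 60)
    event = rng.integers(0, 2, 60)
    event[0] = 1
    risk = rng.normal(size=60)
    # lifelines scores predicted survival time (higher = later), hence -risk
    assert concordance_index(time, event, risk) == pytest.approx(
        ll_cindex(time, -risk, event)
    )


def test_no_comparable_pairs_raises():
    with pytest.raises(ValueError, match="comparable"):
        concordance_index([1.0, 1.0], [0, 0], [0.5, 0.2])


# ----------------------------------------------------------- time-dependent AUC
def test_reduces_to_plain_auc_without_censoring():
    rng = np.random.default_rng(7)
    time = rng.exponential(5, 40) + 0.1
    event = np.ones(40, int)
    risk = rng.normal(size=40)
    tau = float(np.median(time))
    cases = (time <= tau)
    controls = time > tau
    gt = (risk[cases][:, None] > risk[controls][None, :]).mean()
    assert time_dependent_auc(time, event, risk, tau) == pytest.approx(gt)


def test_perfect_separation_gives_one():
    time = np.array([1.0, 2.0, 3.0, 8.0, 9.0, 10.0])
    event = np.array([1, 1, 1, 0, 0, 0])
    risk = np.array([5.0, 4.0, 3.0, 0.0, -1.0, -2.0])
    assert time_dependent_auc(time, event, risk, 5.0) == 1.0


def test_hand_computed_ipcw_instance():
    """n=10 with censoring before the horizon; weights from a hand-rolled
    censoring Kaplan-Meier (left limits)."""
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.5, 6.0, 7.0, 8.0, 9.0, 10.0])
    event = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 1])
    risk = np.array([2.0, 1.8, 1.5, 1.2, 0.9, 0.6, 0.3, 0.2, 0.1, 0.0])
    tau = 5.0
    # censoring KM: drops at t=2 (10 at risk) and t=4 (8 at risk)
    # G(t-): t=1: 1.0; t=3: 0.9; t=5.5: 0.9*7/8
    g_left = {1.0: 1.0, 3.0: 0.9}
    cases = [0, 2]  # events at 1.0 and 3.0
    controls = list(range(4, 10))  # time > 5
    num = den = 0.0
    for i in cases:
        w = 1.0 / g_left[time[i]]
        den += w * len(controls)
        for j in controls:
            num += w * (risk[i] > risk[j])
    assert time_dependent_auc(time, event, risk, tau) == pytest.approx(num / den)


def test_agrees_with_scikit_survival():
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    rng = np.random.default_rng(8)
    n = 150
    time = rng.weibull(1.5, n) * 8 + 0.01
    cens = rng.exponential(8, n)
    obs = np.minimum(time, cens)
    event = (time <= cens).astype(int)
    risk = -np.log(time) + rng.normal(0, 0.5, n)
    y = Surv.from_arrays(event.astype(bool), obs)
    tau = 5.0
    auc, _ = cumulative_dynamic_auc(y, y, risk, [tau])
    assert time_dependent_auc(obs, event, risk, tau) == pytest.approx(
        float(auc[0]), abs=1e-8
    )


def test_degenerate_horizon_raises():
    with pytest.raises(ValueError, match="case"):
        time_dependent_auc([1.0, 2.0], [0, 0], [0.1, 0.2], 5.0)


# --------------------------------------------------------------- dichotomizer
def test_median_split_and_threshold_convention():
    train = np.arange(1.0, 11.0)
    groups, thr = dichotomize_biomarker(train, train)
    assert thr == 5.5
    assert (groups == "low").sum() == 5 and (groups == "high").sum() == 5
    groups, _ = dichotomize_biomarker(train, np.array([5.5]))
    assert groups[0] == "low"  # exactly-at-threshold -> low


def test_shifted_apply_distribution_follows_threshold():
    rng = np.random.default_rng(9)
    train = rng.normal(0, 1, 200)
    apply_risk = rng.normal(2, 1, 200)
    groups, thr = dichotomize_biomarker(train, apply_risk)
    assert (groups == "high").sum() == (apply_risk > thr).sum() > 150


def test_constant_risks_warn_all_low():
    with pytest.warns(UserWarning, match="constant"):
        groups, _ = dichotomize_biomarker(np.ones(5), np.ones(3))
    assert np.all(groups == "low")


# ------------------------------------------------------------------ KM curves
def test_km_equals_empirical_survival_without_censoring():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.ones(4, int)
    curves, _, _ = km_curves(time, event, np.array(["a"] * 4))
    c = curves["a"].set_index("time")["survival"]
    assert c.loc[2.0] == pytest.approx(0.5)
    assert c.loc[4.0] == pytest.approx(0.0)


def test_km_textbook_product_limit_value():
    # times (6, 7, 10+, 13, 16+): S(13) = (4/5)(3/4)(1/2) = 0.3
    time = np.array([6.0, 7.0, 10.0, 13.0, 16.0])
    event = np.array([1, 1, 0, 1, 0])
    curves, _, _ = km_curves(time, event, np.array(["g"] * 5))
    c = curves["g"].set_index("time")["survival"]
    assert c.loc[13.0] == pytest.approx(0.3)
    surv = curves["g"]["survival"].to_numpy()
    assert np.all(np.diff(surv) <= 1e-12)  # non-increasing
    assert curves["g"]["survival"].iloc[0] == pytest.approx(1.0)  # S(0) = 1


def test_identical_groups_have_null_logrank():
    time = np.tile(np.arange(1.0, 21.0), 2)
    event = np.tile(np.array([1, 0] * 10), 2)
    groups = np.repeat(["low", "high"], 20)
    _, stat, p = km_curves(time, event, groups)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p > 0.99


def test_empty_group_raises():
    with pytest.raises(ValueError, match="non-empty"):
        km_curves(np.array([1.0]), np.array([1]), np.array([]))


# --------------------------------------------------------------- cox screening
def _simulate_ph(n, log_hr, seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    u = rng.uniform(size=n)
    t = 8.0 * (-np.log(u) * np.exp(-log_hr * x)) ** (1 / 1.5)
    c = rng.exponential(10.0, n)
    return pd.DataFrame(
        {"x": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)}
    )


def test_hr_is_exp_of_coefficient():
    df = _simulate_ph(500, 1.0, 0)
    res = cox_screen(df, "time", "event", ["x"], mode="univariate")
    assert res["HR"].iloc[0] == pytest.approx(np.exp(res["coef"].iloc[0]))


def test_recovers_binary_log_hazard_ratio():
    df = _simulate_ph(2000, 1.0, 1)
    res = cox_screen(df, "time", "event", ["x"], mode="univariate")
    assert res["coef"].iloc[0] == pytest.approx(1.0, abs=0.12)
    assert res["CI_lower"].iloc[0] < np.e < res["CI_upper"].iloc[0]


def test_multivariate_restricts_to_univariate_significant():
    rng = np.random.default_rng(2)
    df = _simulate_ph(800, 1.0, 3)
    df["noise"] = rng.normal(size=len(df))
    res = cox_screen(df, "time", "event", ["x", "noise"], mode="multivariate")
    assert "x" in res["covariate"].tolist()
    assert "noise" not in res["covariate"].tolist()


def test_singular_design_names_collinear_columns():
    df = _simulate_ph(200, 1.0, 4)
    df["x2"] = df["x"] * 2.0
    with pytest.raises(np.linalg.LinAlgError, match="x2"):
        cox_screen(df, "time", "event", ["x", "x2"], mode="multivariate", alpha_select=1.1)
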