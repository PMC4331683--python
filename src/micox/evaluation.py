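"""Survival-prediction evaluation: time-dependent AUC, risk groups,
log-rank test, Kaplan-Meier curves.

The time-dependent ROC uses the cumulative-cases / dynamic-controls
convention: at evaluation time t, cases are samples with an observed
event by t and controls are samples still under observation beyond t;
samples censored at or before t are excluded at that t. AUC(t) is the
probability that a random case outranks a random control on the
prognostic index (Mann-Whitney concordance, ties counted 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

from .data import SurvivalData
from .netcox import _as_survival

__all__ = [
    "TimeAUC",
    "RiskGroups",
    "td_auc",
    "split_risk_groups",
    "logrank_test",
    "km_curve",
]


@dataclass(frozen=True)
class TimeAUC:
    """AUC(t) over a grid of evaluation times, plus their unweighted mean."""

    eval_times: np.ndarray
    auc_at_t: np.ndarray
    mean_auc: float

    def __post_init__(self) -> None:
        if self.eval_times.shape != self.auc_at_t.shape:
            raise ValueError("eval_times and auc_at_t must align")


@dataclass(frozen=True)
class RiskGroups:
    """Top/bottom risk strata by prognostic index (default 40% / 40%)."""

    high_ids: np.ndarray
    low_ids: np.ndarray
    fraction: float


def _mann_whitney_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    # concordance of cases over controls with ties at 1/2
    scores = np.concatenate([cases, controls])
    ranks = rankdata(scores)
    r_cases = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    u = r_cases - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def td_auc(pi, surv, eval_times=None) -> TimeAUC:
    """Time-dependent AUC of prognostic indices against survival outcomes.

    Parameters
    ----------
    pi : array-like
        Prognostic index per sample (higher = predicted higher risk).
    surv : SurvivalData (or compatible)
        True follow-up and event status, aligned with ``pi``.
    eval_times : array-like, optional
        Times at which to evaluate; defaults to the distinct observed
        event times. Times where the case or control set is empty are
        skipped.
    """
    sv = _as_survival(surv)
    pi = np.asarray(pi, dtype=float)
    if pi.size != len(sv):
        raise ValueError("pi and survival data are not aligned")
    if sv.n_events == 0:
        warnings.warn("no observed events; time-dependent AUC is undefined", stacklevel=2)
        return TimeAUC(eval_times=np.array([]), auc_at_t=np.array([]), mean_auc=np.nan)
    if eval_times is None:
        eval_times = np.unique(sv.time[sv.status == 1])
    eval_times = np.asarray(eval_times, dtype=float)
    times, aucs = [], []
    for t in eval_times:
        case_mask = (sv.time <= t) & (sv.status == 1)
        control_mask = sv.time > t
        if not case_mask.any() or not control_mask.any():
            continue
        times.append(t)
        aucs.append(_mann_whitney_auc(pi[case_mask], pi[control_mask]))
    times = np.asarray(times)
    aucs = np.asarray(aucs)
    mean = float(aucs.mean()) if aucs.size else np.nan
    return TimeAUC(eval_times=times, auc_at_t=aucs, mean_auc=mean)


def split_risk_groups(pi, ids=None, fraction: float = 0.40) -> RiskGroups:
    """Rank samples by PI descending; top block = high risk, bottom = low.

    Each group holds ``floor(fraction * n)`` samples. Ties are broken by
    stable input order.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    pi = np.asarray(pi, dtype=float)
    n = pi.size
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    if ids.size != n:
        raise ValueError("ids and pi are not aligned")
    k = int(np.floor(fraction * n))
    if k < 1:
        raise ValueError("groups would be empty at this fraction")
    order = np.argsort(-pi, kind="stable")
    return RiskGroups(
        high_ids=ids[order[:k]], low_ids=ids[order[n - k :]], fraction=float(fraction)
    )


def logrank_test(groups: RiskGroups, surv) -> tuple[float, float]:
    """Two-group log-rank test between the high- and low-risk strata.

    Accumulates observed minus expected events in group 1 and the
    hypergeometric variance across distinct event times; the statistic
    (O1 - E1)^2 / V is referred to chi-square with 1 df.
    """
    sv = _as_survival(surv)
    s_high = sv.subset(groups.high_ids)
    s_low = sv.subset(groups.low_ids)
    if len(s_high) == 0 or len(s_low) == 0:
        raise ValueError("both risk groups must be non-empty")
    time = np.concatenate([s_high.time, s_low.time])
    status = np.concatenate([s_high.status, s_low.status])
    grp = np.concatenate([np.ones(len(s_high)), np.zeros(len(s_low))])
    if status.sum() == 0:
        raise ValueError("no events in either group; log-rank test is undefined")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[status == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        n1 = grp[at_risk].sum()
        ev = (time == t) & (status == 1)
        d = ev.sum()
        d1 = (ev & (grp == 1)).sum()
        o_minus_e += d1 - d * n1 / n_t
        if n_t > 1:
            var += d * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d) / (n_t - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def km_curve(surv) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimator.

    Returns step coordinates ``(times, survival)`` starting at (0, 1);
    the curve is non-increasing and drops only at event times.
    """
    sv = _as_survival(surv)
    event_times = np.unique(sv.time[sv.status == 1])
    s = 1.0
    times = [0.0]
    probs = [1.0]
    for t in event_times:
        n_t = (sv.time >= t).sum()
        d = ((sv.time == t) & (sv.status == 1)).sum()
        s *= 1.0 - d / n_t
        times.append(float(t))
        probs.append(float(s))
    return np.asarray(times), np.asarray(probs)
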