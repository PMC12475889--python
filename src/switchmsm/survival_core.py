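"""Estimation machinery on counting-process data.

Nelson-Aalen cumulative-hazard estimation honouring delayed entry, a Cox
proportional-hazards fit for the single binary arm covariate (Breslow tie
handling, Newton-Raphson), and the two-sided Wald test used by the
simulation study.  The Cox fit is written directly against the risk-set
structure of the two-arm problem so that thousands of replicate fits stay
cheap; an optional subject-clustered sandwich standard error accounts for
the correlation a clone shares with its source patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .augmentation import RecordSet
from .cohort_sim import ARM_TD

__all__ = [
    "NAEstimate",
    "CoxFit",
    "FitError",
    "MonotoneLikelihoodError",
    "ConvergenceError",
    "nelson_aalen",
    "cox_fit",
    "wald_reject",
]


class FitError(RuntimeError):
    """The model could not be fit on the given records."""


class MonotoneLikelihoodError(FitError):
    """Partial likelihood is monotone in beta (no events, or events in one
    arm only / no between-arm comparison at any event time)."""


class ConvergenceError(FitError):
    """Newton-Raphson failed to reach the gradient tolerance."""


# ---------------------------------------------------------------------------
# Nelson-Aalen


@dataclass
class NAEstimate:
    """Right-continuous step estimate of a cumulative hazard.

    ``cumulative[k]`` is the estimate just after ``jump_times[k]``;
    ``increments[k] = d_k / n_k`` with ``d_k`` the events at the jump and
    ``n_k = risk_sizes[k]`` the number under observation just prior.
    ``entry_sorted``/``exit_sorted`` retain the interval data so the
    at-risk process remains evaluable.
    """

    jump_times: np.ndarray
    increments: np.ndarray
    cumulative: np.ndarray
    risk_sizes: np.ndarray
    entry_sorted: np.ndarray
    exit_sorted: np.ndarray

    def __len__(self) -> int:
        return len(self.jump_times)

    def at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Cumulative hazard A(t) (right-continuous step evaluation)."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        out = cum[idx]
        return float(out) if np.isscalar(t) else out

    def at_risk(self, t: float | np.ndarray) -> int | np.ndarray:
        """Number of rows with ``entry < t <= exit`` (at risk just prior to t)."""
        t_arr = np.asarray(t, dtype=float)
        n = np.searchsorted(self.exit_sorted, t_arr, side="left")
        m = np.searchsorted(self.entry_sorted, t_arr, side="left")
        out = (len(self.exit_sorted) - n) - (len(self.entry_sorted) - m)
        return int(out) if np.isscalar(t) else out

    @property
    def terminal(self) -> float:
        return float(self.cumulative[-1]) if len(self) else 0.0


def _na_from_arrays(entry: np.ndarray, exit: np.ndarray, event: np.ndarray) -> NAEstimate:
    entry = np.asarray(entry, dtype=float)
    exit = np.asarray(exit, dtype=float)
    event = np.asarray(event, dtype=bool)
    if np.any(exit <= entry):
        raise ValueError("every record must satisfy exit > entry")
    ev_times = exit[event]
    if ev_times.size == 0:
        return NAEstimate(
            jump_times=np.empty(0),
            increments=np.empty(0),
            cumulative=np.empty(0),
            risk_sizes=np.empty(0, dtype=np.int64),
            entry_sorted=np.sort(entry),
            exit_sorted=np.sort(exit),
        )
    times, counts = np.unique(ev_times, return_counts=True)
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit)
    # at risk just prior to t: entry < t <= exit
    n_exit_ge = len(exit_sorted) - np.searchsorted(exit_sorted, times, side="left")
    n_entry_ge = len(entry_sorted) - np.searchsorted(entry_sorted, times, side="left")
    risk = n_exit_ge - n_entry_ge
    inc = counts / risk
    return NAEstimate(
        jump_times=times,
        increments=inc,
        cumulative=np.cumsum(inc),
        risk_sizes=risk.astype(np.int64),
        entry_sorted=entry_sorted,
        exit_sorted=exit_sorted,
    )


def nelson_aalen(records: RecordSet, *, pool_timescales: bool = False) -> NAEstimate:
    """Nelson-Aalen cumulative-hazard estimate with delayed entry.

    A row contributes to risk sets only on ``(entry, exit]``; jumps occur
    at event times with increment (events at t) / (at risk just prior).

    Records carrying both ``original`` and ``restarted`` timescale tags do
    not share a clock, and pooling them is rejected unless
    ``pool_timescales=True`` — the deliberate setting used to study the
    clock-restarting estimators, which do exactly that pooling.
    """
    if len(records) == 0:
        return _na_from_arrays(np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    if not pool_timescales and len(records.timescales()) > 1:
        raise ValueError(
            "records mix restarted and original timescales; pass "
            "pool_timescales=True to analyse them on one clock anyway"
        )
    return _na_from_arrays(records.entry, records.exit, records.event)


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate


@dataclass
class CoxFit:
    """Proportional-hazards fit of arm (TD vs CD) on counting-process data."""

    beta_hat: float
    se: float
    hr: float
    wald_z: float
    p_value: float
    n_rows: int
    n_events: int
    robust: bool
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "beta_hat": self.beta_hat,
            "se": self.se,
            "hr": self.hr,
            "wald_z": self.wald_z,
            "p_value": self.p_value,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            "robust": self.robust,
        }


def _risk_counts(entry, exit, x, event):
    """Breslow risk-set summaries at each distinct event time.

    Returns (times, d1, d0, n1, n0): events and at-risk counts per arm,
    at-risk meaning entry < t <= exit.
    """
    ev = exit[event]
    evx = x[event]
    times = np.unique(ev)
    d1 = np.zeros(len(times))
    d0 = np.zeros(len(times))
    idx = np.searchsorted(times, ev)
    np.add.at(d1, idx, evx.astype(float))
    np.add.at(d0, idx, (~evx).astype(float))

    def at_risk(mask):
        en = np.sort(entry[mask])
        ex = np.sort(exit[mask])
        ge_ex = len(ex) - np.searchsorted(ex, times, side="left")
        ge_en = len(en) - np.searchsorted(en, times, side="left")
        return (ge_ex - ge_en).astype(float)

    return times, d1, d0, at_risk(x), at_risk(~x)


def _breslow_loglik(beta: float, d1, d0, n1, n0):
    """(loglik, gradient, information) of the Breslow partial likelihood."""
    eb = np.exp(beta)
    s0 = n0 + n1 * eb
    d = d1 + d0
    ll = float(np.sum(d1) * beta - np.sum(d * np.log(s0)))
    xbar = n1 * eb / s0
    grad = float(np.sum(d1) - np.sum(d * xbar))
    info = float(np.sum(d * xbar * (1.0 - xbar)))
    return ll, grad, info


def cox_fit(
    records: RecordSet,
    robust: bool = False,
    *,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit the arm hazard ratio by Cox partial likelihood.

    Newton-Raphson with step-halving on the Breslow partial likelihood of
    the single binary covariate ``arm == TD``; delayed entry is honoured
    through the ``(entry, exit]`` risk sets.  With ``robust=True`` the
    standard error is the subject-clustered (sandwich) estimate grouping
    all rows — clones included — of one patient; the default model-based
    error replicates a naive fit that treats clones as independent.
    """
    x = records.arm == ARM_TD
    event = records.event
    n_events = int(event.sum())
    if n_events == 0:
        raise MonotoneLikelihoodError("no events in the dataset")
    if not (x.any() and (~x).any()):
        raise FitError("both arms must be present")
    times, d1, d0, n1, n0 = _risk_counts(records.entry, records.exit, x, event)
    # Identification: events in both arms and a two-arm risk set at >=1 event time.
    if d1.sum() == 0 or d0.sum() == 0:
        raise MonotoneLikelihoodError("events occur in only one arm")
    comparable = (n1 > 0) & (n0 > 0)
    if not comparable.any():
        raise MonotoneLikelihoodError("no event time has both arms at risk")

    beta = 0.0
    ll, grad, info = _breslow_loglik(beta, d1, d0, n1, n0)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if abs(grad) < tol:
            break
        if info <= 0:
            raise ConvergenceError("non-positive information")
        step = grad / info
        # step-halving on likelihood decrease
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _breslow_loglik(cand, d1, d0, n1, n0)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood")
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    else:
        if abs(grad) >= tol:
            raise ConvergenceError(f"gradient {grad:.3e} above tolerance after {max_iter} iterations")
    # A hazard ratio beyond e^15 on real risk sets means the likelihood is
    # effectively monotone (events separate the arms after some time).
    if not np.isfinite(beta) or abs(beta) > 15:
        raise MonotoneLikelihoodError("likelihood is monotone (|beta| diverged)")

    var_model = 1.0 / info
    if robust:
        var = _sandwich_variance(records, x, beta, times, d1, d0, n1, n0, info)
    else:
        var = var_model
    se = float(np.sqrt(var))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(
        beta_hat=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        wald_z=float(z),
        p_value=float(p),
        n_rows=len(records),
        n_events=n_events,
        robust=robust,
        n_iter=n_iter,
    )


def _sandwich_variance(records, x, beta, times, d1, d0, n1, n0, info):
    """Subject-grouped sandwich variance for the single-covariate fit.

    Score residual of row i:
    ``U_i = delta_i (x_i - xbar(T_i)) - exp(beta x_i) *
    sum_{t_k in (entry_i, exit_i]} (d_k / S0_k) (x_i - xbar(t_k))``;
    rows are summed within subject before squaring.
    """
    eb = np.exp(beta)
    s0 = n0 + n1 * eb
    xbar = n1 * eb / s0
    d = d1 + d0
    a = np.concatenate([[0.0], np.cumsum(d / s0)])          # sum d_k/S0_k
    b = np.concatenate([[0.0], np.cumsum(d * xbar / s0)])   # sum d_k xbar_k/S0_k
    lo = np.searchsorted(times, records.entry, side="right")
    hi = np.searchsorted(times, records.exit, side="right")
    sum_a = a[hi] - a[lo]
    sum_b = b[hi] - b[lo]
    xf = x.astype(float)
    expx = np.where(x, eb, 1.0)
    u = -expx * (xf * sum_a - sum_b)
    ev = records.event
    if ev.any():
        idx = np.searchsorted(times, records.exit[ev])
        u[ev] += xf[ev] - xbar[idx]
    _, inv = np.unique(records.subject_id, return_inverse=True)
    u_subj = np.bincount(inv, weights=u)
    meat = float(np.sum(u_subj**2))
    return meat / (info * info)


def wald_reject(fit: CoxFit, alpha: float = 0.05) -> bool:
    """Two-sided Wald test of beta = 0: reject iff p_value < alpha."""
    if not np.isfinite(fit.se) or fit.se <= 0:
        raise FitError("Wald test requires a finite positive standard error")
    return bool(fit.p_value < alpha)
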