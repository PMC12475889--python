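"""Multistate (illness-death) decomposition of the switching estimators.

Each approach's Cox hazard ratio can be rewritten as a ratio of composite
cause-specific hazards of the illness-death model *initial exposure ->
switch -> adverse event*.  The numerator (and, for the overlapping
approach, the denominator) is an empirical mixture of the failure hazard
of initiators and the post-switch failure hazard of prevalent users,
weighted at every instant by the at-risk composition:

    hierarchical:  [ P_TD(t) a_TD(t) + (1-P_TD(t)) a_sw->TD(t) ] / a_CD^censored(t)
    overlapping:   [ P_TD(t) a_TD(t) + (1-P_TD(t)) a_sw->TD(t) ]
                 / [ P_CD(t) a_CD(t) + (1-P_CD(t)) a_sw->CD(t) ]

where the switched-stratum hazards are taken on the analysis timescale —
shifted back to 0 when the clock is restarted, left-truncated otherwise.
Mixing prevalent with incident users on a restarted clock is exactly what
distorts the composite when the hazard is time-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augmentation import (
    HIERARCHICAL,
    OVERLAPPING,
    TIMESCALE_ORIGINAL,
    TIMESCALE_RESTARTED,
)
from .cohort_sim import ARM_CD, ARM_TD, Cohort
from .survival_core import NAEstimate, _na_from_arrays

# Transition-curve labels (state 0 = initial exposure, 1 = switched, 2 = AE)
TD_STARTER = "td_starter_failure"            # TD starters 0->2, full follow-up
CD_CENSORED = "cd_failure_censored_at_switch"  # CD starters 0->2, censored at switch
CD_STARTER = "cd_starter_failure"            # CD starters 0->2, full follow-up
SWITCHED_TO_TD = "switched_to_td_failure"    # 1->2 after a CD->TD switch
SWITCHED_TO_CD = "switched_to_cd_failure"    # 1->2 after a TD->CD switch
SWITCH_CD_TO_TD = "switch_cd_to_td"          # 0->1 out of CD
SWITCH_TD_TO_CD = "switch_td_to_cd"          # 0->1 out of TD


@dataclass
class TransitionCurveSet:
    """Stratified Nelson-Aalen curves underlying one approach's estimator."""

    approach: str
    restart_clock: bool
    timescale: str
    curves: dict[str, NAEstimate]
    numerator_labels: tuple[str, ...]
    denominator_labels: tuple[str, ...]
    n_subjects: int
    clones_at_time_zero: int
    horizon: float

    def at_risk_table(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        """At-risk counts (rows with ``entry <= t < exit``) per stratum.

        The left-continuous convention makes the ``t = 0`` row show the
        full starting risk set: the simulated subjects plus, on a
        restarted timescale, the clones injected at time 0.
        """
        grid = _default_grid(self.horizon, include_zero=True) if grid is None else np.asarray(grid, float)
        cols: dict[str, np.ndarray] = {"time": grid}
        for label, est in self.curves.items():
            cols[label] = _at_risk_from(est, grid)
        fail = [l for l in self.curves if l in (self.numerator_labels + self.denominator_labels)]
        cols["total"] = np.sum([cols[l] for l in fail], axis=0)
        return pd.DataFrame(cols)

    def curve_frame(self) -> pd.DataFrame:
        """Tidy long-format table of every curve's jumps (for CSV/plots)."""
        parts = []
        for label, est in self.curves.items():
            parts.append(
                pd.DataFrame(
                    {
                        "curve": label,
                        "time": est.jump_times,
                        "increment": est.increments,
                        "cumulative": est.cumulative,
                        "risk_size": est.risk_sizes,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["curve", "time", "increment", "cumulative", "risk_size"]
        )


@dataclass
class HRDecomposition:
    """Composite-hazard representation of the approach's hazard ratio.

    ``numerator``/``denominator`` are composite *cumulative* hazards on
    the grid (mixtures of the stratum curves weighted by at-risk
    fractions); ``hr_curve`` is their ratio, NaN where the denominator
    risk set is empty.
    """

    grid: np.ndarray
    p_td: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray
    hr_curve: np.ndarray
    p_cd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time": self.grid,
            "p_td": self.p_td,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "hr": self.hr_curve,
        }
        if self.p_cd is not None:
            cols["p_cd"] = self.p_cd
        return pd.DataFrame(cols)


def _default_grid(horizon: float, n: int = 200, include_zero: bool = False) -> np.ndarray:
    grid = np.linspace(0.0, horizon, n + 1)
    return grid if include_zero else grid[1:]


def _at_risk_from(est: NAEstimate, grid: np.ndarray) -> np.ndarray:
    # entry <= t < exit (left-continuous from the right)
    le_en = np.searchsorted(est.entry_sorted, grid, side="right")
    le_ex = np.searchsorted(est.exit_sorted, grid, side="right")
    return le_en - le_ex


def _stratum(cohort: Cohort, mask: np.ndarray, entry, exit, event) -> NAEstimate:
    keep = mask & (np.asarray(exit) > np.asarray(entry))
    return _na_from_arrays(
        np.broadcast_to(np.asarray(entry, float), mask.shape)[keep],
        np.asarray(exit, float)[keep],
        np.asarray(event, bool)[keep],
    )


def transition_curves(
    cohort: Cohort, approach: str, restart_clock: bool
) -> TransitionCurveSet:
    """Stratified transition-hazard curves for one approach and clock setting.

    Failure strata (0->2 and 1->2) are exactly the record strata whose
    pooled Nelson-Aalen estimates enter the approach's hazard-ratio
    decomposition; 0->1 curves give the switching hazard.  Post-switch
    strata live on the restarted clock (``(0, T-s]``) when
    ``restart_clock`` else on the original clock with delayed entry
    ``(s, T]``.
    """
    td = cohort.initial_arm == ARM_TD
    cd = ~td
    sw = cohort.observed_switch
    T = cohort.followup_time
    e = cohort.event
    s = np.where(np.isfinite(cohort.switch_time), cohort.switch_time, np.inf)
    zeros = np.zeros(len(cohort))

    def post_switch(mask):
        if restart_clock:
            return _stratum(cohort, mask, zeros, T - np.where(mask, s, 0.0), e)
        return _stratum(cohort, mask, np.where(mask, s, 0.0), T, e)

    def switch_hazard(mask):
        # 0->1: at risk in state 0; the switch is the "event" at time s.
        exit = np.where(mask & sw, s, T)
        return _stratum(cohort, mask, zeros, exit, mask & sw)

    curves: dict[str, NAEstimate] = {}
    curves[TD_STARTER] = _stratum(cohort, td, zeros, T, e)
    curves[SWITCHED_TO_TD] = post_switch(cd & sw)
    curves[SWITCH_CD_TO_TD] = switch_hazard(cd)
    if approach == HIERARCHICAL:
        exit_cd = np.where(cd & sw, s, T)
        curves[CD_CENSORED] = _stratum(cohort, cd, zeros, exit_cd, e & ~(cd & sw))
        num, den = (TD_STARTER, SWITCHED_TO_TD), (CD_CENSORED,)
    elif approach == OVERLAPPING:
        curves[CD_STARTER] = _stratum(cohort, cd, zeros, T, e)
        curves[SWITCHED_TO_CD] = post_switch(td & sw)
        curves[SWITCH_TD_TO_CD] = switch_hazard(td)
        num, den = (TD_STARTER, SWITCHED_TO_TD), (CD_STARTER, SWITCHED_TO_CD)
    else:
        raise ValueError(f"unknown approach {approach!r}")

    n_clones0 = 0
    if restart_clock:
        labels = [SWITCHED_TO_TD] + ([SWITCHED_TO_CD] if approach == OVERLAPPING else [])
        n_clones0 = int(sum(len(curves[l].exit_sorted) for l in labels))
    return TransitionCurveSet(
        approach=approach,
        restart_clock=restart_clock,
        timescale=TIMESCALE_RESTARTED if restart_clock else TIMESCALE_ORIGINAL,
        curves=curves,
        numerator_labels=num,
        denominator_labels=den,
        n_subjects=len(cohort),
        clones_at_time_zero=n_clones0,
        horizon=float(T.max()) if len(cohort) else 0.0,
    )


def _composite_cumulative(
    primary: NAEstimate, switched: NAEstimate, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mixture cumulative hazard int_0^t [P(u) dA_prim(u) + (1-P(u)) dA_sw(u)].

    P(u) is the at-risk fraction of the primary (initiator) stratum among
    both strata just prior to u, so the mixture coincides with the pooled
    Nelson-Aalen estimate of the combined records.  Returns the composite
    on the grid and P evaluated at the grid points.
    """
    jumps = []
    for est, is_primary in ((primary, True), (switched, False)):
        for t, inc in zip(est.jump_times, est.increments):
            jumps.append((t, inc, is_primary))
    jumps.sort()
    comp_times = np.array([j[0] for j in jumps])
    comp_incs = np.empty(len(jumps))
    for i, (t, inc, is_primary) in enumerate(jumps):
        r_p = primary.at_risk(t)
        r_s = switched.at_risk(t)
        tot = r_p + r_s
        w = r_p / tot if tot else np.nan
        comp_incs[i] = (w if is_primary else 1.0 - w) * inc
    cum = np.concatenate([[0.0], np.cumsum(comp_incs)])
    comp = cum[np.searchsorted(comp_times, grid, side="right")]
    r_p_grid = primary.at_risk(grid).astype(float)
    r_s_grid = switched.at_risk(grid).astype(float)
    tot = r_p_grid + r_s_grid
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, r_p_grid / tot, np.nan)
    return comp, p


def hr_decomposition(
    curveset: TransitionCurveSet, grid: np.ndarray | None = None
) -> HRDecomposition:
    """Evaluate the composite hazard-ratio representation on a time grid.

    Cumulative composite hazards are used rather than raw increments (the
    increments are noisy atoms); under proportional hazards the ratio at
    the horizon approximates the Cox hazard ratio of the corresponding
    augmented dataset.  Grid points with an empty denominator risk set
    are flagged as NaN.
    """
    if grid is None:
        grid = _default_grid(curveset.horizon)
    grid = np.asarray(grid, dtype=float)
    num, p_td = _composite_cumulative(
        curveset.curves[TD_STARTER], curveset.curves[SWITCHED_TO_TD], grid
    )
    p_cd = None
    if curveset.approach == HIERARCHICAL:
        den_est = curveset.curves[CD_CENSORED]
        den = den_est.at(grid)
    else:
        den, p_cd = _composite_cumulative(
            curveset.curves[CD_STARTER], curveset.curves[SWITCHED_TO_CD], grid
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.where(den > 0, num / den, np.nan)
    return HRDecomposition(
        grid=grid, p_td=p_td, numerator=num, denominator=den, hr_curve=hr, p_cd=p_cd
    )


def empirical_mixture_hazard(cohort: Cohort, arm_of_origin: str) -> NAEstimate:
    """Marginal post-switch failure hazard on the restarted clock.

    Each observed switcher out of ``arm_of_origin`` contributes the
    interval ``(0, T_i - s_i]`` with their own switch time ``s_i``; the
    pooled Nelson-Aalen estimate over these shifted records is the
    observable mixture of the individual post-switch hazards.  With a
    common switch time it reduces exactly to the single shifted
    switched-stratum curve.  No switchers yields an empty estimate.
    """
    if arm_of_origin not in (ARM_TD, ARM_CD):
        raise ValueError(f"unknown arm {arm_of_origin!r}")
    mask = cohort.observed_switch & (cohort.initial_arm == arm_of_origin)
    shifted = cohort.followup_time - np.where(mask, cohort.switch_time, 0.0)
    return _stratum(cohort, mask, np.zeros(len(cohort)), shifted, cohort.event)
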