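"""Nelson-Aalen and Cox machinery against hand computation, brute force,
and lifelines as an independent implementation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from switchmsm import (
    ARM_CD,
    ARM_TD,
    FitError,
    MonotoneLikelihoodError,
    Record,
    RecordSet,
    ScenarioConfig,
    augment_hierarchical,
    cox_fit,
    nelson_aalen,
    simulate_cohort,
    wald_reject,
)

from conftest import SEED, binom_band


def recset(rows):
    """rows: (arm, entry, exit, event[, subject_id])"""
    return RecordSet.from_records(
        [
            Record(
                subject_id=r[4] if len(r) > 4 else i,
                clone=False,
                arm=r[0],
                entry=r[1],
                exit=r[2],
                event=r[3],
            )
            for i, r in enumerate(rows)
        ]
    )


# ---------------------------------------------------------------------------
# Nelson-Aalen


def test_na_hand_example():
    """Jumps 1/3 at t=1 and 1/2 at t=2 for the classic 3-row example."""
    est = nelson_aalen(recset([(ARM_TD, 0, 1, True), (ARM_TD, 0, 2, True),
                               (ARM_TD, 0, 3, False)]))
    np.testing.assert_allclose(est.jump_times, [1, 2])
    np.testing.assert_allclose(est.increments, [1 / 3, 1 / 2])
    assert est.at(0.5) == 0.0
    assert est.at(1.0) == pytest.approx(1 / 3)
    assert est.at(2.7) == pytest.approx(5 / 6)
    assert est.at(3.0) == pytest.approx(5 / 6)
    np.testing.assert_array_equal(est.risk_sizes, [3, 2])


def test_na_left_truncated_single_row():
    est = nelson_aalen(recset([(ARM_TD, 2, 3, True)]))
    assert est.at(2.9) == 0.0
    assert est.at(3.0) == pytest.approx(1.0)
    assert est.at_risk(2.5) == 1
    assert est.at_risk(2.0) == 0


def test_na_no_events_and_empty_input():
    est = nelson_aalen(recset([(ARM_TD, 0, 5, False)]))
    assert len(est) == 0 and est.at(4.0) == 0.0
    empty = nelson_aalen(RecordSet.from_records([]))
    assert empty.terminal == 0.0


def test_na_invariants_on_simulated_data(cohort1):
    recs = augment_hierarchical(cohort1, False)
    est = nelson_aalen(recs)
    assert np.all(np.diff(est.cumulative) > 0)
    assert np.all(est.risk_sizes > 0)
    np.testing.assert_allclose(est.increments, np.diff(np.concatenate([[0], est.cumulative])))
    # each increment is events-at-jump / risk-size
    assert np.all(est.increments * est.risk_sizes >= 1 - 1e-12)


def test_na_matches_naive_no_truncation_implementation(cohort2):
    """With all entries at 0 the estimator equals a naive risk-set count."""
    td = cohort2.initial_arm == ARM_TD
    exit = cohort2.followup_time[td]
    event = cohort2.event[td]
    est = nelson_aalen(recset(
        [(ARM_TD, 0.0, x, e) for x, e in zip(exit, event)]))
    # naive: risk set at t = #(exit >= t)
    times = np.unique(exit[event])
    naive = np.cumsum(
        [np.sum(exit[event] == t) / np.sum(exit >= t) for t in times]
    )
    np.testing.assert_allclose(est.cumulative, naive, rtol=1e-12)


def test_na_matches_lifelines_with_delayed_entry(cohort1):
    lifelines = pytest.importorskip("lifelines")
    recs = augment_hierarchical(cohort1, False)
    mask = recs.arm == ARM_TD
    sub = recs.select(mask)
    naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(sub.exit, event_observed=sub.event, entry=sub.entry)
    est = nelson_aalen(sub, pool_timescales=True)
    grid = np.linspace(0.5, 7.5, 15)
    ours = est.at(grid)
    theirs = naf.cumulative_hazard_at_times(grid).to_numpy()
    np.testing.assert_allclose(ours, theirs, rtol=1e-8)


def test_na_rejects_mixed_timescales(cohort1):
    recs = augment_hierarchical(cohort1, True)
    with pytest.raises(ValueError, match="timescale"):
        nelson_aalen(recs)
    est = nelson_aalen(recs, pool_timescales=True)
    assert est.terminal > 0


# ---------------------------------------------------------------------------
# Cox fit


def brute_force_beta(rows, lo=-5.0, hi=5.0):
    """Independent partial-likelihood maximizer: naive loops + fine grid."""
    def loglik(beta):
        ll = 0.0
        for arm_i, entry_i, exit_i, event_i in rows:
            if not event_i:
                continue
            x_i = 1.0 if arm_i == ARM_TD else 0.0
            denom = 0.0
            for arm_j, entry_j, exit_j, _ in rows:
                if entry_j < exit_i <= exit_j:
                    denom += math.exp(beta * (1.0 if arm_j == ARM_TD else 0.0))
            ll += beta * x_i - math.log(denom)
        return ll

    grid = np.linspace(lo, hi, 20001)
    best = grid[int(np.argmax([loglik(b) for b in grid]))]
    fine = np.linspace(best - 5e-4, best + 5e-4, 2001)
    return fine[int(np.argmax([loglik(b) for b in fine]))]


def test_cox_matches_brute_force_grid_search():
    """Four subjects with interleaved events: MLE to 1e-4 vs grid search."""
    rows = [(ARM_TD, 0, 1, True), (ARM_CD, 0, 2, True),
            (ARM_TD, 0, 3, True), (ARM_CD, 0, 4, True)]
    fit = cox_fit(recset(rows))
    assert fit.beta_hat == pytest.approx(brute_force_beta(rows), abs=1e-4)
    # and with delayed entry
    rows_lt = [(ARM_TD, 0, 1, True), (ARM_CD, 0.5, 2, True),
               (ARM_TD, 1.5, 3, True), (ARM_CD, 0, 4, True), (ARM_CD, 2, 5, False)]
    fit_lt = cox_fit(recset(rows_lt))
    assert fit_lt.beta_hat == pytest.approx(brute_force_beta(rows_lt), abs=1e-4)


def test_cox_identical_arms_gives_zero():
    """Duplicating rows under both labels forces beta = 0 by symmetry."""
    base = [(0.0, 1.0, True), (0.0, 2.0, True), (0.0, 3.0, False), (1.0, 4.0, True)]
    rows = [(ARM_TD, *r) for r in base] + [(ARM_CD, *r) for r in base]
    fit = cox_fit(recset(rows))
    assert fit.beta_hat == pytest.approx(0.0, abs=1e-10)
    assert fit.hr == pytest.approx(1.0)
    assert not wald_reject(fit)


def test_cox_label_swap_flips_sign(cohort2):
    recs = augment_hierarchical(cohort2, True)
    fit = cox_fit(recs)
    swapped = RecordSet(
        subject_id=recs.subject_id, clone=recs.clone,
        arm=np.where(recs.arm == ARM_TD, ARM_CD, ARM_TD).astype("<U2"),
        entry=recs.entry, exit=recs.exit, event=recs.event,
        timescale=recs.timescale,
    )
    fit2 = cox_fit(swapped)
    assert fit2.beta_hat == pytest.approx(-fit.beta_hat, abs=1e-8)
    assert fit2.se == pytest.approx(fit.se, rel=1e-8)


def test_cox_matches_lifelines(cohort2):
    lifelines = pytest.importorskip("lifelines")
    for restart in (True, False):
        recs = augment_hierarchical(cohort2, restart)
        fit = cox_fit(recs)
        df = recs.to_frame()
        df["x"] = (df["arm"] == ARM_TD).astype(float)
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="exit", event_col="event", entry_col="entry",
                formula="x")
        assert fit.beta_hat == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-5)


def test_cox_robust_sandwich_matches_lifelines(cohort2):
    # clustered sandwich cross-check on a restarted dataset (all entries 0)
    lifelines = pytest.importorskip("lifelines")
    recs = augment_hierarchical(cohort2, True)
    fit = cox_fit(recs, robust=True)
    assert fit.robust
    df = recs.to_frame()
    df["x"] = (df["arm"] == ARM_TD).astype(float)
    cph = lifelines.CoxPHFitter()
    cph.fit(df, duration_col="exit", event_col="event", entry_col="entry",
            cluster_col="subject_id", robust=True, formula="x")
    assert fit.se == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-5)
    model = cox_fit(recs, robust=False)
    assert fit.beta_hat == pytest.approx(model.beta_hat)
    assert fit.se != model.se


def test_cox_parameter_recovery_true_hr_2():
    """Two-arm no-switch cohorts with rate ratio 2 recover beta ~ ln 2."""
    cfg = ScenarioConfig(scenario_id=91, shape=1.0, scale=4.0, switch_time=1.0,
                         switch_prop=0.0, seed=SEED)
    coh = simulate_cohort(cfg, 0, arm_scales=(2.0, 4.0))  # TD hazard doubled
    recs = augment_hierarchical(coh, True)
    fit = cox_fit(recs)
    assert abs(fit.beta_hat - math.log(2.0)) < 3 * fit.se
    assert fit.hr == pytest.approx(2.0, rel=0.1)


def test_cox_na_ratio_identity(cohort1):
    """exp(beta) ~ ratio of arm-wise Nelson-Aalen estimates at the horizon."""
    recs = augment_hierarchical(cohort1, False)
    fit = cox_fit(recs)
    tau = recs.exit.max()
    na_td = nelson_aalen(recs.select(recs.arm == ARM_TD), pool_timescales=True)
    na_cd = nelson_aalen(recs.select(recs.arm == ARM_CD), pool_timescales=True)
    assert fit.hr == pytest.approx(na_td.at(tau) / na_cd.at(tau), rel=0.10)


def test_cox_error_taxonomy():
    with pytest.raises(MonotoneLikelihoodError, match="no events"):
        cox_fit(recset([(ARM_TD, 0, 1, False), (ARM_CD, 0, 2, False)]))
    with pytest.raises(MonotoneLikelihoodError):
        cox_fit(recset([(ARM_TD, 0, 1, True), (ARM_CD, 0, 2, False)]))
    with pytest.raises(FitError):
        cox_fit(recset([(ARM_TD, 0, 1, True), (ARM_TD, 0, 2, True)]))
    # events in both arms but never a shared risk set -> no comparison
    with pytest.raises(MonotoneLikelihoodError):
        cox_fit(recset([(ARM_TD, 0, 1, True), (ARM_CD, 2, 3, True)]))
    # events ordered so the likelihood is monotone (arms separate in time)
    with pytest.raises(MonotoneLikelihoodError):
        cox_fit(recset([(ARM_TD, 0, 1, True), (ARM_TD, 0, 2, True),
                        (ARM_CD, 0, 3, True), (ARM_CD, 0, 4, True)]))


def test_wald_boundary_behaviour(cohort1):
    recs = augment_hierarchical(cohort1, False)
    fit = cox_fit(recs)
    # z = 0 -> p = 1 -> never rejected
    null_fit = replace(fit, wald_z=0.0, p_value=1.0)
    assert not wald_reject(null_fit)
    # p exactly at alpha is not a rejection (strict inequality)
    boundary = replace(fit, p_value=0.05)
    assert not wald_reject(boundary)
    assert wald_reject(replace(fit, p_value=0.049))
    # the normal quantile: |z| = 1.959964 sits at p ~ 0.05
    from scipy import stats
    assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)


def test_null_rejection_rate_nominal_without_switching():
    """With no switching the Wald test holds its 5% level (99% band)."""
    cfg = ScenarioConfig(scenario_id=92, shape=1.0, scale=10.0, switch_time=1.0,
                         switch_prop=0.0, n_td=500, n_cd=500, seed=SEED)
    n_reps = 1000
    rejections = 0
    for r in range(n_reps):
        coh = simulate_cohort(cfg, r)
        fit = cox_fit(augment_hierarchical(coh, True))
        rejections += wald_reject(fit)
    lo, hi = binom_band(0.05, n_reps, z=2.576)
    assert lo < rejections / n_reps < hi
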