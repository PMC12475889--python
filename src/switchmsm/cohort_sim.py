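"""Synthetic switching cohorts for the null-hypothesis simulation study.

Two arms of treatment-naive initiators (test drug TD, comparator drug CD)
share one Weibull adverse-event-time distribution: switching is assigned at
baseline, happens at a common fixed time, and has no effect on the event
hazard.  Follow-up is administratively censored at a fixed horizon.  The
only stochastic elements are the latent event time and the baseline switch
assignment, so every departure of an analysis from the nominal test level
is attributable to the dataset construction, not to the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

ARM_TD = "TD"
ARM_CD = "CD"

#: CSV column order for cohort round-trips.
COHORT_COLUMNS = [
    "subject_id",
    "initial_arm",
    "latent_event_time",
    "followup_time",
    "event",
    "switch_assigned",
    "observed_switch",
    "switch_time",
]


class ConfigError(ValueError):
    """A scenario configuration field is invalid; the message names it."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    The Weibull parameterization follows R's ``rweibull``: survival
    ``S(t) = exp(-(t/scale)^shape)`` and hazard
    ``alpha(t) = (shape/scale) * (t/scale)^(shape-1)``, so ``shape = 1``
    gives a constant hazard of ``1/scale`` per year.

    Parameters
    ----------
    scenario_id : int
        Label used in reports and in the random substream key.
    shape, scale : float
        Weibull shape (dimensionless) and scale (years) of the latent
        adverse-event time, identical in both arms under the null.
    switch_time : float
        Common switching time t*_SW in years.  A subject assigned to
        switch actually switches only if still event-free (and uncensored)
        at this time.
    switch_prop : float
        Baseline (assigned) switching proportion in [0, 1], drawn
        independently of the event time.
    n_td, n_cd : int
        Number of TD and CD initiators.
    admin_censor : float
        Administrative censoring horizon in years.
    n_reps : int
        Simulation replicates for a full scenario run.
    seed : int
        Base seed; replicate ``r`` uses the independent substream keyed by
        ``(seed, scenario_id, r)``.
    """

    scenario_id: int
    shape: float
    scale: float
    switch_time: float
    switch_prop: float
    n_td: int = 3000
    n_cd: int = 3000
    admin_censor: float = 8.0
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shape", "scale", "switch_time", "admin_censor"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if not 0.0 <= self.switch_prop <= 1.0:
            raise ConfigError(f"switch_prop must lie in [0, 1], got {self.switch_prop!r}")
        if self.switch_time > self.admin_censor:
            raise ConfigError(
                f"switch_time ({self.switch_time}) must not exceed admin_censor ({self.admin_censor})"
            )
        for name in ("n_td", "n_cd", "n_reps"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer, got {getattr(self, name)!r}")
        if self.seed < 0:
            raise ConfigError(f"seed must be non-negative, got {self.seed!r}")

    @property
    def n_total(self) -> int:
        return self.n_td + self.n_cd

    def survival(self, t: float | np.ndarray) -> float | np.ndarray:
        """Event-free probability S(t) = exp(-(t/scale)^shape)."""
        return np.exp(-np.power(np.asarray(t, dtype=float) / self.scale, self.shape))


@dataclass(frozen=True)
class Subject:
    """One simulated patient, convenient for hand-built test cases."""

    subject_id: int
    initial_arm: str
    latent_event_time: float
    followup_time: float
    event: bool
    switch_assigned: bool
    observed_switch: bool
    switch_time: float = math.nan  # defined only when observed_switch


@dataclass
class Cohort:
    """Column-oriented cohort container (one entry per subject).

    Arrays are aligned; ``switch_time`` is NaN for subjects without an
    observed switch.
    """

    subject_id: np.ndarray
    initial_arm: np.ndarray
    latent_event_time: np.ndarray
    followup_time: np.ndarray
    event: np.ndarray
    switch_assigned: np.ndarray
    observed_switch: np.ndarray
    switch_time: np.ndarray

    def __len__(self) -> int:
        return len(self.subject_id)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_observed_switchers(self) -> int:
        return int(self.observed_switch.sum())

    def subjects(self) -> Iterator[Subject]:
        for i in range(len(self)):
            yield Subject(
                subject_id=int(self.subject_id[i]),
                initial_arm=str(self.initial_arm[i]),
                latent_event_time=float(self.latent_event_time[i]),
                followup_time=float(self.followup_time[i]),
                event=bool(self.event[i]),
                switch_assigned=bool(self.switch_assigned[i]),
                observed_switch=bool(self.observed_switch[i]),
                switch_time=float(self.switch_time[i]),
            )

    @classmethod
    def from_subjects(cls, subjects: Iterable[Subject]) -> "Cohort":
        subs = list(subjects)
        return cls(
            subject_id=np.array([s.subject_id for s in subs], dtype=np.int64),
            initial_arm=np.array([s.initial_arm for s in subs], dtype="<U2"),
            latent_event_time=np.array([s.latent_event_time for s in subs], dtype=float),
            followup_time=np.array([s.followup_time for s in subs], dtype=float),
            event=np.array([s.event for s in subs], dtype=bool),
            switch_assigned=np.array([s.switch_assigned for s in subs], dtype=bool),
            observed_switch=np.array([s.observed_switch for s in subs], dtype=bool),
            switch_time=np.array([s.switch_time for s in subs], dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in COHORT_COLUMNS})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        return cls(
            subject_id=frame["subject_id"].to_numpy(np.int64),
            initial_arm=frame["initial_arm"].to_numpy("<U2"),
            latent_event_time=frame["latent_event_time"].to_numpy(float),
            followup_time=frame["followup_time"].to_numpy(float),
            event=frame["event"].to_numpy(bool),
            switch_assigned=frame["switch_assigned"].to_numpy(bool),
            observed_switch=frame["observed_switch"].to_numpy(bool),
            switch_time=frame["switch_time"].to_numpy(float),
        )


def _substream(config: ScenarioConfig, rep_index: int) -> np.random.Generator:
    # Counter-based substream: independent, reproducible per replicate.
    key = np.random.SeedSequence(entropy=config.seed, spawn_key=(config.scenario_id, rep_index))
    return np.random.default_rng(key)


def simulate_cohort(
    config: ScenarioConfig,
    rep_index: int = 0,
    *,
    arm_scales: tuple[float, float] | None = None,
) -> Cohort:
    """Simulate one replicate cohort of ``n_td + n_cd`` subjects.

    Event times are i.i.d. Weibull(shape, scale), identical in both arms
    and unaffected by switching (the null hypothesis).  Switch assignment
    is a baseline Bernoulli(switch_prop) draw independent of the event
    time; an assigned switcher is an *observed* switcher only if still
    under follow-up strictly beyond ``switch_time``.

    Parameters
    ----------
    config : ScenarioConfig
    rep_index : int
        Replicate counter (>= 0); the draw is deterministic given
        ``(config.seed, config.scenario_id, rep_index)``.
    arm_scales : (float, float), optional
        ``(scale_td, scale_cd)`` override for generating data under an
        alternative hypothesis (used for parameter-recovery checks only);
        default is the shared null scale.
    """
    if rep_index < 0:
        raise ConfigError(f"rep_index must be non-negative, got {rep_index!r}")
    rng = _substream(config, rep_index)
    n = config.n_total
    arm = np.concatenate(
        [np.full(config.n_td, ARM_TD, dtype="<U2"), np.full(config.n_cd, ARM_CD, dtype="<U2")]
    )
    if arm_scales is None:
        scale = config.scale
    else:
        scale = np.where(arm == ARM_TD, float(arm_scales[0]), float(arm_scales[1]))
    # rweibull convention: S(t) = exp(-(t/scale)^shape)
    latent = scale * rng.weibull(config.shape, size=n)
    assigned = rng.random(n) < config.switch_prop
    followup = np.minimum(latent, config.admin_censor)
    event = latent <= config.admin_censor
    observed = assigned & (followup > config.switch_time)
    switch_time = np.where(observed, config.switch_time, np.nan)
    return Cohort(
        subject_id=np.arange(n, dtype=np.int64),
        initial_arm=arm,
        latent_event_time=latent,
        followup_time=followup,
        event=event,
        switch_assigned=assigned,
        observed_switch=observed,
        switch_time=switch_time,
    )


def expected_event_count(config: ScenarioConfig) -> float:
    """Closed-form expected number of observed events by the horizon.

    ``(n_td + n_cd) * (1 - exp(-(admin_censor/scale)^shape))`` — the
    analytic companion used to calibrate and sanity-check the simulator.
    """
    p = 1.0 - math.exp(-((config.admin_censor / config.scale) ** config.shape))
    return config.n_total * p


def expected_observed_switch_prop(config: ScenarioConfig) -> float:
    """Expected observed-switcher fraction: switch_prop * S(switch_time).

    Strictly below the assigned proportion whenever events (or censoring)
    can precede the switch time.
    """
    return config.switch_prop * float(config.survival(config.switch_time))


def expected_clone_count(config: ScenarioConfig, arms: Sequence[str] = (ARM_CD,)) -> float:
    """Expected number of observed switchers out of the given initial arms."""
    p = expected_observed_switch_prop(config)
    n = sum(config.n_td if a == ARM_TD else config.n_cd for a in arms)
    return n * p


# ---------------------------------------------------------------------------
# Scenario configuration IO


def _packaged_scenario_path() -> Path:
    return Path(__file__).parent / "data" / "table1_scenarios.yaml"


def load_scenarios(
    path: str | Path | None = None,
    *,
    seed: int = 0,
    n_reps: int | None = None,
) -> dict[int, ScenarioConfig]:
    """Load scenario configurations from YAML, keyed by scenario id.

    Without ``path`` the packaged default grid of 22 null scenarios is
    used.  ``seed`` and ``n_reps`` override the corresponding fields of
    every scenario (YAML entries may also set them explicitly).
    """
    path = _packaged_scenario_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["scenarios"] if isinstance(raw, dict) else raw
    known = {f.name for f in fields(ScenarioConfig)}
    out: dict[int, ScenarioConfig] = {}
    for entry in entries:
        unknown = set(entry) - known
        if unknown:
            raise ConfigError(f"unknown scenario field(s): {sorted(unknown)}")
        cfg = ScenarioConfig(**{**{"seed": seed}, **entry})
        if n_reps is not None:
            cfg = replace(cfg, n_reps=n_reps)
        if cfg.scenario_id in out:
            raise ConfigError(f"duplicate scenario_id {cfg.scenario_id}")
        out[cfg.scenario_id] = cfg
    return out
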