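"""Assist-as-needed closed-loop simulation.

Simulates the trial state machine of the rehabilitation system against a
simulated patient.  Within a trial the patient progresses toward the
exercise target at a constant rate until their ability-plus-assistance
capacity is exhausted; if the target is out of reach an error response
(event *e*) fires at the projected-failure moment, its detection (event
*d*, sampled from a detection profile mirroring the asynchronous detector's
measured rates) triggers a one-level assistance boost (event *i*, x -> x+1)
under which the robot completes the remainder, and assistance returns to
the minimum level x when the trial finishes (event *f*).  Trials in which
the error fires only near the very end, or which complete without any
boost, trigger the adaptation step (event *s*): the minimum assistance
level is decreased and/or the exercise difficulty target increased.

All continuous quantities (ability, assistance effect, progress rate) are
normalised abstractions; every rate is config-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ernbci.io_core import ValidationError

logger = logging.getLogger("ernbci")


@dataclass
class AssistanceState:
    """Controller state: minimum assistance level and exercise difficulty."""

    x: int = 5                     # minimum assistance level (units of steps)
    target: float = 0.8            # normalised completion requirement
    x_max: int = 10
    target_step: float = 0.1
    assist_gain: float = 0.1       # capacity added per assistance level

    def __post_init__(self):
        if self.x < 0:
            raise ValidationError("assistance level cannot be negative")
        if not 0 < self.target <= 1:
            raise ValidationError("target must be in (0, 1]")

    @property
    def boost(self) -> int:
        return self.x + 1


@dataclass
class PatientModel:
    """Simulated patient and detection profile.

    ``ability`` is the fraction of a full exercise achievable unaided;
    assistance level x adds ``assist_gain * x``.  The detection profile
    (p_correct, p_incorrect, p_none) mirrors an asynchronous-detector
    IDR report; latency is the detection delay after the error fires,
    as a fraction of the trial duration.
    """

    ability: float = 0.3
    ability_gain: float = 0.02     # per completed trial
    p_correct: float = 0.9
    p_incorrect: float = 0.04
    p_none: float = 0.06
    detection_latency: float = 0.05
    latency_jitter: float = 0.0
    speed: float = 1.2             # progress units per trial duration

    def __post_init__(self):
        p = self.p_correct + self.p_incorrect + self.p_none
        if abs(p - 1.0) > 1e-9:
            raise ValidationError(f"detection probabilities sum to {p}, not 1")
        if not 0 <= self.ability <= 1:
            raise ValidationError("ability must be in [0, 1]")


@dataclass
class TrialLog:
    """Events and measurements of one simulated trial (times in trial units)."""

    trial_index: int
    x: int
    target: float
    t_e: float | None = None       # error response elicited
    t_d: float | None = None       # response detected
    t_i: float | None = None       # assistance increased to x+1
    t_f: float | None = None       # trial finished, assistance back to x
    t_spurious: float | None = None
    boost_duration: float = 0.0
    completion_fraction: float = 0.0
    detection: str | None = None   # correct | incorrect | none | None
    outcome: str = ""              # success | assisted | incomplete
    adapted: bool = False

    def validate_ordering(self) -> None:
        chain = [t for t in (self.t_e, self.t_d, self.t_i, self.t_f)
                 if t is not None]
        if any(b < a for a, b in zip(chain, chain[1:])):
            raise ValidationError(f"event ordering violated: {chain}")


def run_trial(patient: PatientModel, state: AssistanceState,
              rng=None, trial_index: int = 0, duration: float = 1.0,
              ema_latency: float | None = None) -> TrialLog:
    """Simulate one exercise trial.

    The patient's capacity at minimum assistance is
    ``cap = min(1, ability + assist_gain * x)``.  If ``cap`` covers the
    target the trial succeeds unassisted.  Otherwise progress stalls at
    ``t_e = cap / speed`` and the error response fires; on (correct)
    detection the boost level completes the remainder at the same rate.
    With ``ema_latency`` set, the boost is triggered at the smoothed
    detection timing instead of the raw one.
    """
    rng = np.random.default_rng(rng)
    log = TrialLog(trial_index=trial_index, x=state.x, target=state.target)
    v = patient.speed / duration
    cap = min(1.0, patient.ability + state.assist_gain * state.x)

    if cap >= state.target:
        log.t_f = state.target / v
        log.completion_fraction = 1.0
        log.outcome = "success"
        return log

    t_e = cap / v
    kind = rng.choice(["correct", "incorrect", "none"],
                      p=[patient.p_correct, patient.p_incorrect,
                         patient.p_none])
    log.detection = str(kind)
    if kind == "correct":
        log.t_e = t_e
        latency = patient.detection_latency
        if patient.latency_jitter > 0:
            latency = max(0.0, rng.normal(latency, patient.latency_jitter))
        if ema_latency is not None:
            latency = ema_latency
        log.t_d = log.t_i = t_e + latency * duration
        log.t_f = log.t_i + (state.target - cap) / v
        log.boost_duration = log.t_f - log.t_i
        log.completion_fraction = 1.0
        log.outcome = "assisted"
    elif kind == "incorrect":
        # spurious detection: unwarranted boost before any error fires
        log.t_spurious = log.t_i = float(rng.uniform(0.0, t_e))
        done = min(cap, v * log.t_i)
        log.t_f = log.t_i + (state.target - done) / v
        log.boost_duration = log.t_f - log.t_i
        log.completion_fraction = 1.0
        log.outcome = "assisted"
    else:
        log.t_e = t_e
        log.t_f = duration
        log.completion_fraction = cap / state.target
        log.outcome = "incomplete"
    log.validate_ordering()
    return log


def update_policy(state: AssistanceState, log: TrialLog,
                  late_fraction: float = 0.9,
                  completion_threshold: float = 0.95,
                  duration: float = 1.0) -> AssistanceState:
    """Trial-to-trial adaptation (event *s*).

    If the error fired only near the very end of the trial, or the exercise
    completed without any boost (verified through the completion-fraction
    signal, the motion-tracking stand-in), the patient no longer needs the
    current support: decrease the minimum assistance level one step and
    raise the difficulty target one step.  Otherwise the state is unchanged.
    """
    late_e = log.t_e is not None and log.t_e >= late_fraction * duration
    unassisted = (log.boost_duration == 0.0
                  and log.completion_fraction >= completion_threshold)
    if not (late_e or unassisted):
        return state
    return replace(state,
                   x=max(0, state.x - 1),
                   target=min(1.0, state.target + state.target_step))


def ema_update(previous: float | None, raw: float, alpha: float = 0.3) -> float:
    """Exponential moving average of raw detection timings."""
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    if previous is None:
        return raw
    return alpha * raw + (1.0 - alpha) * previous


def simulate_program(patient: PatientModel, state: AssistanceState,
                     n_trials: int = 40, seed=None, duration: float = 1.0,
                     use_ema: bool = False, ema_alpha: float = 0.3,
                     adapt: bool = True) -> list[TrialLog]:
    """Sequential trials with ability growth and policy adaptation.

    With ``use_ema`` the boost trigger uses the exponential moving average
    of the observed detection latencies instead of each trial's raw timing.
    """
    rng = np.random.default_rng(seed)
    patient = replace(patient)
    logs = []
    ema = None
    for k in range(n_trials):
        log = run_trial(patient, state, rng, trial_index=k, duration=duration,
                        ema_latency=ema if use_ema else None)
        if use_ema and log.detection == "correct" and log.t_d is not None \
                and log.t_e is not None:
            ema = ema_update(ema, (log.t_d - log.t_e) / duration, ema_alpha)
        log.x = state.x
        log.target = state.target
        if adapt:
            new_state = update_policy(state, log, duration=duration)
            log.adapted = new_state is not state
            state = new_state
        if log.completion_fraction >= 1.0:
            patient = replace(patient, ability=min(
                1.0, patient.ability + patient.ability_gain))
        logs.append(log)
    logger.info("simulate_program: %d trials, final ability %.2f, x=%d",
                n_trials, patient.ability, state.x)
    return logs


def logs_to_frame(logs: list[TrialLog]) -> pd.DataFrame:
    """Trial logs as a flat table (for TSV export)."""
    return pd.DataFrame([{
        "trial": lg.trial_index, "x": lg.x, "target": lg.target,
        "t_e": lg.t_e, "t_d": lg.t_d, "t_i": lg.t_i, "t_f": lg.t_f,
        "boost_duration": lg.boost_duration,
        "completion_fraction": lg.completion_fraction,
        "detection": lg.detection, "outcome": lg.outcome,
        "adapted": lg.adapted,
    } for lg in logs])
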