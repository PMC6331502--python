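"""Weighted one-up/one-down staircase with reversal-mean JND estimation.

The procedure presents two intervals per trial (standard vs. manipulated, in
random order); the tracked quantity is the stimulus difference ``delta``.
Each incorrect response increases delta by the phase's up-step, each correct
response decreases it by the down-step.  With up:down = 3:1 in both phases
the track equilibrates where P(correct) = up / (up + down) = 0.75
(Kaernbach's weighted up-down rule).  After ``phase_switch_reversals``
reversals the coarse steps give way to fine steps, the run continues for
``terminal_reversals`` further reversals, and the JND is the arithmetic mean
of delta at those final reversal trials.  A full test is five runs (one per
vowel); the test JND is the mean of the five run JNDs.

Default configurations: pitch — initial 100 cents, steps 30/10 then 6/2;
timbre — initial 12 (SER-%), steps 3/1 then 0.6/0.2.  Both switch after 4
reversals and terminate after 10 more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer_model import Observer, respond

__all__ = [
    "StaircaseConfig", "TrialRecord", "RunResult", "TestResult",
    "PITCH_STAIRCASE", "TIMBRE_STAIRCASE",
    "detect_reversals", "next_delta", "run_staircase", "estimate_jnd",
    "run_test", "trials_to_frame", "StaircaseError",
]


class StaircaseError(RuntimeError):
    """Raised for non-converging runs or insufficient reversal data."""


@dataclass(frozen=True)
class StaircaseConfig:
    initial_delta: float
    up_step_phase1: float
    down_step_phase1: float
    up_step_phase2: float
    down_step_phase2: float
    phase_switch_reversals: int = 4
    terminal_reversals: int = 10
    delta_floor: float = 1.0
    delta_ceiling: float = 2400.0
    max_trials: int = 10_000

    def __post_init__(self):
        steps = (self.up_step_phase1, self.down_step_phase1,
                 self.up_step_phase2, self.down_step_phase2)
        if any(s <= 0 for s in steps):
            raise ValueError("all step sizes must be positive")
        if not (self.up_step_phase1 > self.down_step_phase1
                and self.up_step_phase2 > self.down_step_phase2):
            raise ValueError("up step must exceed down step (target above 50%)")
        if self.phase_switch_reversals < 1 or self.terminal_reversals < 2:
            raise ValueError("need >=1 switch reversal and >=2 terminal reversals")
        if not (0.0 <= self.delta_floor < self.delta_ceiling):
            raise ValueError("require 0 <= delta_floor < delta_ceiling")
        if not (self.delta_floor <= self.initial_delta <= self.delta_ceiling):
            raise ValueError("initial_delta outside [floor, ceiling]")

    def up_step(self, phase: int) -> float:
        return self.up_step_phase1 if phase == 1 else self.up_step_phase2

    def down_step(self, phase: int) -> float:
        return self.down_step_phase1 if phase == 1 else self.down_step_phase2


PITCH_STAIRCASE = StaircaseConfig(
    initial_delta=100.0, up_step_phase1=30.0, down_step_phase1=10.0,
    up_step_phase2=6.0, down_step_phase2=2.0,
    delta_floor=1.0, delta_ceiling=2400.0)

TIMBRE_STAIRCASE = StaircaseConfig(
    initial_delta=12.0, up_step_phase1=3.0, down_step_phase1=1.0,
    up_step_phase2=0.6, down_step_phase2=0.2,
    delta_floor=0.1, delta_ceiling=30.0)


@dataclass(frozen=True)
class TrialRecord:
    index: int          # 1-based trial number
    delta: float        # stimulus difference presented
    order: int          # interval holding the manipulated stimulus (1 or 2)
    response: int       # interval the observer chose
    correct: bool
    is_reversal: bool
    phase: int


@dataclass(frozen=True)
class RunResult:
    trials: tuple[TrialRecord, ...]
    reversal_deltas: tuple[float, ...]
    jnd: float


@dataclass(frozen=True)
class TestResult:
    run_results: tuple[RunResult, ...]
    jnd_mean: float


def detect_reversals(correct_sequence) -> list[int]:
    """1-based indices of reversal trials (correctness differs from previous)."""
    seq = list(correct_sequence)
    if not seq:
        raise ValueError("empty response sequence")
    return [i + 1 for i in range(1, len(seq)) if bool(seq[i]) != bool(seq[i - 1])]


def next_delta(current: float, correct: bool, phase: int,
               config: StaircaseConfig) -> float:
    """Delta for the next trial: down-step on correct, up-step on incorrect, clamped."""
    step = -config.down_step(phase) if correct else config.up_step(phase)
    return min(max(current + step, config.delta_floor), config.delta_ceiling)


def run_staircase(observer: Observer, config: StaircaseConfig,
                  seed=None) -> RunResult:
    """Simulate one adaptive run against ``observer``; reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    total_target = config.phase_switch_reversals + config.terminal_reversals
    trials: list[TrialRecord] = []
    delta = config.initial_delta
    phase = 1
    reversals = 0
    prev_correct: bool | None = None
    for index in range(1, config.max_trials + 1):
        order = int(rng.integers(1, 3))
        response = respond(observer, delta, order, rng)
        if response not in (1, 2):
            raise ValueError(f"observer returned invalid interval {response!r}")
        correct = response == order
        is_reversal = prev_correct is not None and correct != prev_correct
        if is_reversal:
            reversals += 1
        trials.append(TrialRecord(index, delta, order, response, correct,
                                  is_reversal, phase))
        if reversals >= total_target:
            run = tuple(trials)
            rev_deltas = _final_reversal_deltas(run, config)
            return RunResult(run, rev_deltas, float(np.mean(rev_deltas)))
        if reversals >= config.phase_switch_reversals:
            phase = 2  # fine steps from the first trial after the switch reversal
        delta = next_delta(delta, correct, phase, config)
        prev_correct = correct
    raise StaircaseError(
        f"staircase did not reach {total_target} reversals within "
        f"{config.max_trials} trials")


def _final_reversal_deltas(trials, config: StaircaseConfig) -> tuple[float, ...]:
    rev = [t.delta for t in trials if t.is_reversal]
    needed = config.phase_switch_reversals + config.terminal_reversals
    if len(rev) < needed:
        raise StaircaseError(
            f"only {len(rev)} reversals recorded; need {needed} for a JND estimate")
    return tuple(rev[-config.terminal_reversals:])


def estimate_jnd(trials, config: StaircaseConfig) -> float:
    """Mean delta over the final ``terminal_reversals`` reversal trials."""
    return float(np.mean(_final_reversal_deltas(tuple(trials), config)))


def run_test(observer: Observer, config: StaircaseConfig, n_runs: int = 5,
             seed=None) -> TestResult:
    """Run ``n_runs`` staircases (one per vowel in the real test) and average."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    child_seeds = root.spawn(n_runs)
    runs = tuple(run_staircase(observer, config, seed=s) for s in child_seeds)
    return TestResult(runs, float(np.mean([r.jnd for r in runs])))


def trials_to_frame(trials) -> pd.DataFrame:
    """Trial log as a CSV-ready DataFrame."""
    return pd.DataFrame([{
        "trial": t.index, "delta": t.delta, "order": t.order,
        "response": t.response, "correct": t.correct,
        "is_reversal": t.is_reversal, "phase": t.phase,
    } for t in trials])
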