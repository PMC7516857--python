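"""Motion-detection and sound-localization environments.

These two tasks define the study conditions for everything downstream:
stimulus sets, update schedules, fitness, and the recordings from which
transfer entropy is later estimated.

Motion detection (MD)
    A Reichardt-style delay-and-compare classification.  Two sensors
    (N0, N1) receive a 2-step binary pattern; 3 of the 16 patterns are
    preferred-direction (PD), 3 are null-direction (ND), 10 are
    stationary.  The brain is updated once after the first stimulus and
    twice after the second (the second stimulus stays clamped during both
    updates).  The sum of the two output neurons codes the class:
    0 = ND, 1 = stationary, 2 = PD.

Sound localization (SL)
    A Jeffress-style interaural-time-difference task.  Two sensors receive
    one pulse each, lagged by −2…+2 update steps over a 3-step schedule;
    the brain is updated once per step, and the answer is read one-hot
    from five designated output neurons (N11–N15), one per source angle.

Recordings
    Each trial contributes 4 snapshots of the full 16-neuron state: the
    all-quiescent initial state plus the state after each of the 3
    updates.  MD → 16×4 = 64 snapshots (48 within-trial transitions);
    SL → 5×4 = 20 snapshots (15 transitions).  Brains are deterministic,
    so one recording per trial suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .info_theory import TransitionDataset
from .markov_brain import Brain, update

__all__ = [
    "Trial",
    "EvalResult",
    "MD_LABELS",
    "md_trials",
    "md_evaluate",
    "sl_trials",
    "sl_evaluate",
    "run_trial",
    "record",
]

MD_LABELS = {0: "ND", 1: "stationary", 2: "PD"}

# Two-step patterns (a, b, c, d): sensors read (a, b) at the first step and
# (c, d) at the second.
_PD_PATTERNS = {(1, 0, 0, 1), (1, 1, 0, 1), (0, 0, 1, 0)}
_ND_PATTERNS = {(0, 1, 1, 0), (1, 1, 1, 0), (0, 1, 1, 1)}


@dataclass(frozen=True)
class Trial:
    """One stimulus schedule: a clamp per update step, plus its class label."""

    name: str
    label: int
    category: str
    clamps: tuple[Mapping[int, int], ...]  # one dict per update (3 updates)


def md_trials(sensors: tuple[int, int] = (0, 1)) -> list[Trial]:
    """All 16 motion-detection trials, partitioned 3 PD / 3 ND / 10 stationary."""
    s0, s1 = sensors
    trials = []
    for a, b, c, d in product((0, 1), repeat=4):
        pat = (a, b, c, d)
        if pat in _PD_PATTERNS:
            label, cat = 2, "PD"
        elif pat in _ND_PATTERNS:
            label, cat = 0, "ND"
        else:
            label, cat = 1, "stationary"
        first = {s0: a, s1: b}
        second = {s0: c, s1: d}
        # one update on the first stimulus, two on the (held) second
        trials.append(
            Trial(
                name=f"{a}{b}->{c}{d}",
                label=label,
                category=cat,
                clamps=(first, second, second),
            )
        )
    return trials


def sl_trials(
    lags: Sequence[int] = (-2, -1, 0, 1, 2), sensors: tuple[int, int] = (0, 1)
) -> list[Trial]:
    """Sound-localization trials: one pulse per ear with an interaural lag.

    Lag L (in update steps) places the N0 (left) pulse at step
    ``1 + max(0, −L)`` and the N1 (right) pulse at step ``1 + max(0, L)``
    (1-based); lag +2 → N0 fires at step 1 and N1 at step 3.  Labels are
    the lag indices 0…len(lags)−1, one per source angle.
    """
    s0, s1 = sensors
    trials = []
    for label, lag in enumerate(lags):
        t0 = max(0, -lag)  # 0-based pulse step for the left ear
        t1 = max(0, lag)
        if max(t0, t1) > 2:
            raise ValueError(f"lag {lag} does not fit in a 3-step schedule")
        clamps = tuple(
            {s0: 1 if k == t0 else 0, s1: 1 if k == t1 else 0} for k in range(3)
        )
        trials.append(
            Trial(name=f"lag{lag:+d}", label=label, category=f"lag{lag:+d}", clamps=clamps)
        )
    return trials


def run_trial(brain: Brain, trial: Trial) -> np.ndarray:
    """Snapshots of one trial: the all-quiescent start plus one per update."""
    state = np.zeros(brain.n_neurons, dtype=np.uint8)
    snaps = [state]
    for clamp in trial.clamps:
        state = update(brain, state, clamp)
        snaps.append(state)
    return np.stack(snaps)


def record(brain: Brain, trials: Sequence[Trial]) -> TransitionDataset:
    """Record a behaving brain over ``trials`` (pure function of its inputs)."""
    return TransitionDataset(
        [run_trial(brain, t) for t in trials], n_neurons=brain.n_neurons
    )


@dataclass(frozen=True)
class EvalResult:
    fitness: float
    per_trial: tuple[dict, ...]


def md_evaluate(brain: Brain, trials: Sequence[Trial] | None = None) -> EvalResult:
    """Fraction of the 16 MD trials classified correctly.

    The response is the sum of the brain's two output neurons at the final
    state (0 = ND, 1 = stationary, 2 = PD).
    """
    if len(brain.outputs) != 2:
        raise ValueError("motion detection needs exactly 2 designated output neurons")
    if trials is None:
        trials = md_trials(sensors=(brain.sensory[0], brain.sensory[1]))
    rows = []
    n_correct = 0
    for trial in trials:
        final = run_trial(brain, trial)[-1]
        response = int(final[brain.outputs[0]]) + int(final[brain.outputs[1]])
        ok = response == trial.label
        n_correct += ok
        rows.append(
            {"trial": trial.name, "category": trial.category, "label": trial.label,
             "response": response, "correct": bool(ok)}
        )
    return EvalResult(fitness=n_correct / len(trials), per_trial=tuple(rows))


def sl_evaluate(brain: Brain, trials: Sequence[Trial] | None = None) -> EvalResult:
    """Fraction of the 5 SL trials answered with the correct one-hot output."""
    if len(brain.outputs) != 5:
        raise ValueError("sound localization needs exactly 5 designated output neurons")
    if trials is None:
        trials = sl_trials(sensors=(brain.sensory[0], brain.sensory[1]))
    rows = []
    n_correct = 0
    for trial in trials:
        final = run_trial(brain, trial)[-1]
        pattern = tuple(int(final[o]) for o in brain.outputs)
        ok = pattern == tuple(1 if i == trial.label else 0 for i in range(len(brain.outputs)))
        n_correct += ok
        rows.append(
            {"trial": trial.name, "category": trial.category, "label": trial.label,
             "response": pattern, "correct": bool(ok)}
        )
    return EvalResult(fitness=n_correct / len(trials), per_trial=tuple(rows))
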