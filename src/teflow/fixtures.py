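"""Hand-built and random circuits with known ground truth.

Every pipeline stage (update semantics, logic-table extraction, influence
maps, task evaluation, knockouts, TE estimation) is testable on these
fixtures without running any evolution.  The two solver circuits are our
own constructions: ``md_solver`` implements the delay-and-compare motif of
a Reichardt detector (copy the first stimulus into memory neurons, then
combine delayed and fresh signals), and ``sl_solver`` a Jeffress-style
array of delay lines feeding per-angle coincidence (AND) detectors.
"""

from __future__ import annotations

import random
from typing import Sequence

from .gate_catalog import GATE_CATALOG, Gate, TruthTable
from .markov_brain import Brain

__all__ = ["FIXTURE_NAMES", "build_named_fixture", "single_gate_brain", "random_brain"]


def single_gate_brain(
    table: TruthTable,
    inputs: tuple[int, int] = (0, 1),
    output: int = 2,
    n_neurons: int = 16,
    sensory: tuple[int, ...] = (0, 1),
    outputs: tuple[int, ...] = (14, 15),
) -> Brain:
    """A brain containing exactly one gate."""
    return Brain(
        gates=[Gate(inputs, output, tuple(table))],
        n_neurons=n_neurons,
        sensory=sensory,
        outputs=outputs,
    )


_COPY_X = (0, 0, 1, 1)
_AND = (0, 0, 0, 1)
_NOR = (1, 0, 0, 0)
_AND_NOT_XY = (0, 0, 1, 0)   # X AND NOT Y
_OR_NOT_YX = (1, 1, 0, 1)    # (NOT X) OR Y
_XOR = (0, 1, 1, 0)


def _md_solver() -> Brain:
    # Update 1 copies the first stimulus (a, b) into memory neurons N2, N3;
    # update 2 forms the four pair products needed to separate PD from ND;
    # update 3 reads them out.  N14 = NOT(ND indicator), N15 = PD indicator,
    # so the output sum is 0 for ND, 1 for stationary, 2 for PD.
    gates = [
        Gate((0, 1), 2, _COPY_X),       # N2 <- N0  (delay line, a)
        Gate((1, 0), 3, _COPY_X),       # N3 <- N1  (delay line, b)
        Gate((3, 0), 4, _AND),          # N4 <- b AND c        (at update 2)
        Gate((2, 1), 5, _AND),          # N5 <- a AND d
        Gate((2, 1), 6, _NOR),          # N6 <- NOT a AND NOT d
        Gate((0, 3), 7, _AND_NOT_XY),   # N7 <- c AND NOT b
        Gate((4, 5), 14, _OR_NOT_YX),   # N14 <- NOT(b AND c) OR (a AND d)
        Gate((5, 0), 15, _AND_NOT_XY),  # N15 <- (a AND d) AND NOT c ...
        Gate((6, 7), 15, _AND),         # ... OR (NOT a AND NOT d AND c AND NOT b)
    ]
    return Brain(gates=gates, sensory=(0, 1), outputs=(14, 15))


def _sl_solver() -> Brain:
    # Two 2-step delay lines (N0->N2->N3 and N1->N4->N5) plus five
    # coincidence detectors, one per interaural lag.
    gates = [
        Gate((0, 1), 2, _COPY_X),   # N2 <- N0 delayed once
        Gate((2, 0), 3, _COPY_X),   # N3 <- N0 delayed twice
        Gate((1, 0), 4, _COPY_X),   # N4 <- N1 delayed once
        Gate((4, 0), 5, _COPY_X),   # N5 <- N1 delayed twice
        Gate((0, 5), 11, _AND),     # lag -2: left pulse now, right 2 steps ago
        Gate((2, 5), 12, _AND),     # lag -1
        Gate((3, 5), 13, _AND),     # lag  0
        Gate((3, 4), 14, _AND),     # lag +1
        Gate((3, 1), 15, _AND),     # lag +2
    ]
    return Brain(gates=gates, sensory=(0, 1), outputs=(11, 12, 13, 14, 15))


def _build_fixtures() -> dict:
    fixtures: dict[str, tuple[Brain, dict]] = {}
    for spec in GATE_CATALOG:
        fixtures[f"gate_{spec.key}"] = (
            single_gate_brain(spec.table),
            {"gate": spec.key},
        )
        fixtures[f"gate_{spec.key}_feedback"] = (
            single_gate_brain(spec.table, inputs=(1, 2), output=2, sensory=(0, 1)),
            {"gate": spec.key, "feedback": True},
        )
    fixtures["xor_pair"] = (
        single_gate_brain(_XOR),
        {"edges": {(0, 2), (1, 2)}, "te_blind": True},
    )
    xor_chain = Brain(
        gates=[Gate((0, 1), 2, _XOR), Gate((2, 3), 4, _XOR)],
        sensory=(0, 1),
        outputs=(14, 15),
    )
    fixtures["xor_chain"] = (
        xor_chain,
        {"edges": {(0, 2), (1, 2), (2, 4), (3, 4)}},
    )
    fixtures["md_solver"] = (_md_solver(), {"task": "md", "fitness": 1.0})
    fixtures["sl_solver"] = (_sl_solver(), {"task": "sl", "fitness": 1.0})

    solver = _md_solver()
    dup = Brain(
        gates=list(solver.gates) + [solver.gates[3]],  # duplicate N5 <- a AND d
        sensory=solver.sensory,
        outputs=solver.outputs,
    )
    fixtures["dup_gate"] = (
        dup,
        {"task": "md", "fitness": 1.0,
         "redundant_pair": (3, len(dup.gates) - 1)},
    )
    fixtures["vestigial_input"] = (
        single_gate_brain(_COPY_X),   # second input never matters
        {"edges": {(0, 2)}},
    )
    fixtures["and_feedback"] = (
        single_gate_brain(_AND, inputs=(1, 2), output=2),
        {"edges": {(1, 2), (2, 2)}},
    )
    return fixtures


_FIXTURES = _build_fixtures()
FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def build_named_fixture(name: str) -> tuple[Brain, dict]:
    """A named fixture brain and its expected properties."""
    try:
        brain, expect = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}") from None
    # Return a fresh Brain so callers may mutate gate lists freely.
    return (
        Brain(
            gates=list(brain.gates),
            n_neurons=brain.n_neurons,
            sensory=brain.sensory,
            outputs=brain.outputs,
        ),
        dict(expect),
    )


def random_brain(
    n_gates: int,
    seed: int,
    gate_weights: Sequence[float] | None = None,
    n_neurons: int = 16,
    sensory: tuple[int, ...] = (0, 1),
    outputs: tuple[int, ...] = (14, 15),
    allow_sensor_writes: bool = False,
) -> Brain:
    """Seeded random brain with gate types drawn from the 16-gate catalog."""
    rng = random.Random(seed)
    if gate_weights is None:
        gate_weights = [1.0] * len(GATE_CATALOG)
    if len(gate_weights) != len(GATE_CATALOG):
        raise ValueError("gate_weights must have one entry per catalog gate")
    writable = [
        i for i in range(n_neurons) if allow_sensor_writes or i not in sensory
    ]
    gates = []
    for _ in range(n_gates):
        spec = rng.choices(GATE_CATALOG, weights=gate_weights, k=1)[0]
        gates.append(
            Gate(
                (rng.randrange(n_neurons), rng.randrange(n_neurons)),
                rng.choice(writable),
                spec.table,
            )
        )
    return Brain(gates=gates, n_neurons=n_neurons, sensory=sensory, outputs=outputs)
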