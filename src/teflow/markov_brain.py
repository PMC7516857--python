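"""Deterministic Markov Brains: binary neurons updated by 2-to-1 logic gates.

A Brain is a network of (by default 16) binary neurons whose next state is
computed synchronously from the current state by a list of deterministic
2-input gates.  When several gates write into the same neuron the results
are combined by bitwise OR; a neuron that no gate writes decays to 0
(quiescent).  Memory therefore requires actively rewriting a value each
update.  Sensory neurons are clamped externally: their values are set
before each update, are read by gates, and persist into the next snapshot.

The module also extracts each neuron's exact Boolean function over the full
2^N state space and derives the ground-truth *influence map*: neuron i
influences neuron j iff flipping bit i changes f_j for at least one global
state.  This dependence test automatically discards constant (ZERO/ONE)
gates and vestigial gate inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gate_catalog import Gate, gate_key

__all__ = [
    "Brain",
    "update",
    "logic_table",
    "influence_map",
    "genome_to_brain",
    "brain_to_genome",
    "brain_to_json",
    "brain_from_json",
    "brain_to_dot",
]

Gene = tuple[int, int, int, int, int, int, int]  # (in1, in2, out, t00, t01, t10, t11)


@dataclass
class Brain:
    """A deterministic Markov Brain."""

    gates: list[Gate]
    n_neurons: int = 16
    sensory: tuple[int, ...] = (0, 1)
    outputs: tuple[int, ...] = (14, 15)

    def __post_init__(self) -> None:
        self.sensory = tuple(self.sensory)
        self.outputs = tuple(self.outputs)
        for g in self.gates:
            ids = (*g.inputs, g.output)
            if any(i < 0 or i >= self.n_neurons for i in ids):
                raise ValueError(f"gate {g} references a neuron outside [0, {self.n_neurons})")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Brain):
            return NotImplemented
        return (
            self.gates == other.gates
            and self.n_neurons == other.n_neurons
            and self.sensory == other.sensory
            and self.outputs == other.outputs
        )


def update(
    brain: Brain,
    state: Sequence[int] | np.ndarray,
    clamp: Mapping[int, int] | None = None,
) -> np.ndarray:
    """One synchronous update; returns the next state.

    The clamp (stimulus) is applied to the sensory neurons of ``state``
    before any gate reads it; each non-sensory neuron's next value is the
    OR over all gates writing to it (0 if none writes).  Clamped sensors
    carry their clamped value into the next state, OR-ed with any gate
    writes.
    """
    s = np.array(state, dtype=np.uint8)
    if s.shape != (brain.n_neurons,):
        raise ValueError(f"state has shape {s.shape}, expected ({brain.n_neurons},)")
    if clamp:
        for nid, val in clamp.items():
            if nid not in brain.sensory:
                raise ValueError(f"neuron {nid} is not sensory; cannot clamp it")
            s[nid] = 1 if val else 0
    nxt = np.zeros(brain.n_neurons, dtype=np.uint8)
    for g in brain.gates:
        val = g.table[2 * int(s[g.inputs[0]]) + int(s[g.inputs[1]])]
        nxt[g.output] |= val
    if clamp:
        for nid, val in clamp.items():
            nxt[nid] |= 1 if val else 0
    return nxt


@lru_cache(maxsize=4)
def _all_states(n: int) -> np.ndarray:
    """All 2^n states as a (2^n, n) uint8 matrix; state index i has bit j = neuron j."""
    if n > 20:
        raise ValueError("exhaustive state enumeration limited to n <= 20")
    idx = np.arange(2**n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n, dtype=np.uint32)[None, :]) & 1).astype(np.uint8)


def _bulk_next(gates: Iterable[Gate], states: np.ndarray) -> np.ndarray:
    """Vectorised synchronous update of many states at once (no clamp)."""
    nxt = np.zeros_like(states)
    for g in gates:
        lut = np.asarray(g.table, dtype=np.uint8)
        sel = lut[states[:, g.inputs[0]] * 2 + states[:, g.inputs[1]]]
        np.bitwise_or(nxt[:, g.output], sel, out=nxt[:, g.output])
    return nxt


def logic_table(brain: Brain) -> np.ndarray:
    """Per-neuron Boolean function over all 2^N states.

    Returns a (2^N, N) array ``F`` with ``F[i, j] = f_j(state_i)`` where
    ``state_i`` encodes neuron j in bit j of i, such that
    ``update(brain, state_i)[j] == F[i, j]`` for every state (no clamp).
    """
    return _bulk_next(brain.gates, _all_states(brain.n_neurons))


def influence_map(brain: Brain, zero_sensory_columns: bool = True) -> np.ndarray:
    """Ground-truth binary influence matrix M with M[i, j] = 1 iff i → j.

    An edge i → j exists iff there is a state ``s`` with
    ``f_j(s) != f_j(s with bit i flipped)``.  Sensory columns are zeroed by
    default: sensors are clamped externally at every update during
    behaviour, so nothing inside the circuit can truly influence them.
    The diagonal (self-influence) is kept; detection scoring excludes it
    separately.
    """
    n = brain.n_neurons
    table = logic_table(brain)
    idx = np.arange(2**n, dtype=np.uint32)
    m = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        flipped = table[idx ^ np.uint32(1 << i)]
        m[i] = np.any(flipped != table, axis=0)
    if zero_sensory_columns:
        m[:, list(brain.sensory)] = 0
    return m


# ---------------------------------------------------------------------------
# Genome encoding (structured gene list) and serialization
# ---------------------------------------------------------------------------

def brain_to_genome(brain: Brain) -> tuple[Gene, ...]:
    return tuple((g.inputs[0], g.inputs[1], g.output, *g.table) for g in brain.gates)


def genome_to_brain(
    genome: Sequence[Gene],
    n_neurons: int = 16,
    sensory: tuple[int, ...] = (0, 1),
    outputs: tuple[int, ...] = (14, 15),
) -> Brain:
    gates = [Gate((a, b), o, (t0, t1, t2, t3)) for a, b, o, t0, t1, t2, t3 in genome]
    return Brain(gates=gates, n_neurons=n_neurons, sensory=sensory, outputs=outputs)


def brain_to_json(brain: Brain) -> str:
    return json.dumps(
        {
            "n_neurons": brain.n_neurons,
            "sensory": list(brain.sensory),
            "outputs": list(brain.outputs),
            "genes": [list(gene) for gene in brain_to_genome(brain)],
        }
    )


def brain_from_json(text: str) -> Brain:
    d = json.loads(text)
    return genome_to_brain(
        [tuple(g) for g in d["genes"]],
        n_neurons=d["n_neurons"],
        sensory=tuple(d["sensory"]),
        outputs=tuple(d["outputs"]),
    )


def brain_to_dot(brain: Brain, use_influence: bool = True) -> str:
    """DOT graph of the circuit (influence edges, or raw gate wiring)."""
    lines = ["digraph brain {", "  rankdir=LR;"]
    for s in brain.sensory:
        lines.append(f'  N{s} [shape=box, label="N{s} (sensor)"];')
    for o in brain.outputs:
        lines.append(f'  N{o} [shape=doublecircle, label="N{o}"];')
    if use_influence:
        m = influence_map(brain)
        for i in range(brain.n_neurons):
            for j in range(brain.n_neurons):
                if m[i, j]:
                    lines.append(f"  N{i} -> N{j};")
    else:
        for g in brain.gates:
            label = gate_key(g.table)
            for a in g.inputs:
                lines.append(f'  N{a} -> N{g.output} [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
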