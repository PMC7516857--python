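"""Gate-knockout essentiality assays and theoretical TE-misestimate totals.

A gate is *essential* to a perfectly fit brain when deleting it (with all
its connections) drops task fitness below the intact value.  Given the set
of essential gates, the analytic per-gate table (uniform-input values)
yields a first-order estimate of how much pairwise transfer entropy would
mis-attribute: each essential gate contributes its feedforward misestimate
(or its feedback misestimate when its output neuron is also one of its
inputs), and the matching "correctly attributed" flow.  This is an
approximation — real in-circuit input distributions are not uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .gate_catalog import GATE_CATALOG, gate_analytics, gate_label
from .markov_brain import Brain

__all__ = [
    "knockout_gate",
    "essential_gates",
    "knockout_report",
    "KnockoutReport",
    "GateKnockout",
    "gate_composition",
    "theoretical_misestimate",
    "MisestimateRow",
    "misestimate_summary",
    "mean_ci95",
]

Evaluator = Callable[[Brain], float]


def knockout_gate(brain: Brain, gate_index: int) -> Brain:
    """The mutant brain with one gate (and all its connections) removed."""
    if not 0 <= gate_index < len(brain.gates):
        raise IndexError(f"gate index {gate_index} out of range")
    gates = [g for i, g in enumerate(brain.gates) if i != gate_index]
    return Brain(
        gates=gates,
        n_neurons=brain.n_neurons,
        sensory=brain.sensory,
        outputs=brain.outputs,
    )


@dataclass(frozen=True)
class GateKnockout:
    index: int
    label: str
    mutant_fitness: float
    essential: bool


@dataclass(frozen=True)
class KnockoutReport:
    intact_fitness: float
    gates: tuple[GateKnockout, ...]

    @property
    def essential_indices(self) -> frozenset[int]:
        return frozenset(g.index for g in self.gates if g.essential)


def knockout_report(brain: Brain, evaluate: Evaluator) -> KnockoutReport:
    """Single-knockout scan: re-measure fitness with each gate removed."""
    intact = evaluate(brain)
    rows = []
    for i, g in enumerate(brain.gates):
        mutant_fitness = evaluate(knockout_gate(brain, i))
        rows.append(
            GateKnockout(
                index=i,
                label=gate_label(g.table),
                mutant_fitness=mutant_fitness,
                essential=mutant_fitness < intact,
            )
        )
    return KnockoutReport(intact_fitness=intact, gates=tuple(rows))


def essential_gates(brain: Brain, evaluate: Evaluator) -> set[int]:
    """Indices of gates whose single knockout reduces fitness."""
    return set(knockout_report(brain, evaluate).essential_indices)


def gate_composition(
    brains: Sequence[Brain],
    essential_sets: Sequence[Iterable[int]] | None = None,
    dedup: bool = True,
) -> pd.DataFrame:
    """Per-brain counts of gate family labels (rows = brains, cols = labels).

    ``dedup`` counts gates with identical inputs, output and truth table
    once.  ``essential_sets`` restricts each brain to the given gate
    indices (e.g. the essential set from a knockout scan).
    """
    labels = sorted({spec.label for spec in GATE_CATALOG})
    records = []
    for bi, brain in enumerate(brains):
        keep = set(range(len(brain.gates)))
        if essential_sets is not None:
            keep = set(essential_sets[bi])
        seen = set()
        counts = dict.fromkeys(labels, 0)
        for i, g in enumerate(brain.gates):
            if i not in keep:
                continue
            ident = (g.inputs, g.output, g.table)
            if dedup and ident in seen:
                continue
            seen.add(ident)
            counts[gate_label(g.table)] += 1
        records.append(counts)
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class MisestimateRow:
    """Theoretical TE attribution totals for one brain's essential gates."""

    n_essential: int
    correct_bits: float
    misestimate_bits: float
    per_gate: tuple[dict, ...]

    @property
    def correct_per_gate(self) -> float:
        return self.correct_bits / self.n_essential if self.n_essential else 0.0

    @property
    def misestimate_per_gate(self) -> float:
        return self.misestimate_bits / self.n_essential if self.n_essential else 0.0


def theoretical_misestimate(brain: Brain, essential: Iterable[int]) -> MisestimateRow:
    """Sum per-gate analytic TE misestimates and correct attributions.

    A gate uses the feedback columns iff its output neuron appears among
    its own inputs; otherwise the feedforward columns.  For every gate the
    correctly attributed flow is the total attributable flow minus the
    misestimate, so correct + misestimate adds up to the flow the gate
    carries under uniform inputs.
    """
    correct = 0.0
    wrong = 0.0
    per_gate = []
    for idx in sorted(set(essential)):
        g = brain.gates[idx]
        a = gate_analytics(g.table)
        if g.is_feedback:
            err = a.te_error_fb
            corr = a.te_y_fb + a.processed_fb - err
            wiring = "feedback"
        else:
            err = a.te_error_ff
            corr = a.te_x + a.te_y
            wiring = "feedforward"
        correct += corr
        wrong += err
        per_gate.append(
            {"index": idx, "label": a.label, "wiring": wiring,
             "correct": corr, "misestimate": err}
        )
    return MisestimateRow(
        n_essential=len(per_gate),
        correct_bits=correct,
        misestimate_bits=wrong,
        per_gate=tuple(per_gate),
    )


def mean_ci95(values: Sequence[float]) -> tuple[float, float]:
    """(mean, half-width of the 95% CI) with SE = SD/sqrt(n), SD with ddof=1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return (math.nan, math.nan)
    if arr.size == 1:
        return (float(arr[0]), math.nan)
    se = arr.std(ddof=1) / math.sqrt(arr.size)
    return (float(arr.mean()), float(1.96 * se))


def misestimate_summary(rows: Sequence[MisestimateRow]) -> dict:
    """Cohort means with 95% CIs, per brain and normalized per essential gate."""
    out: dict[str, float] = {"n_brains": len(rows)}
    for name, vals in (
        ("correct_bits", [r.correct_bits for r in rows]),
        ("misestimate_bits", [r.misestimate_bits for r in rows]),
        ("correct_per_gate", [r.correct_per_gate for r in rows]),
        ("misestimate_per_gate", [r.misestimate_per_gate for r in rows]),
        ("n_essential", [float(r.n_essential) for r in rows]),
    ):
        mean, ci = mean_ci95(vals)
        out[f"{name}_mean"] = mean
        out[f"{name}_ci95"] = ci
    return out
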