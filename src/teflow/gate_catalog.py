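"""Catalog of all sixteen deterministic 2-to-1 Boolean gates.

For each gate we compute, analytically, the information quantities that
characterise how well pairwise transfer entropy attributes the flow of
information from the gate's inputs to its output, both for a feedforward
wiring ``Z_{t+1} = f(X_t, Y_t)`` (inputs and the output's own past all iid
uniform) and a feedback wiring ``Z_{t+1} = f(Y_t, Z_t)`` (Y_t, Z_t iid
uniform).  The feedforward TE misestimate is

    error_ff = H(Z_{t+1}) − TE_{X→Z} − TE_{Y→Z} = |I(X_t:Y_t:Z_{t+1}|Z_t)|

which is 1 bit for the cryptographic gates (XOR/XNOR, perfect one-time-pad
encryption), ≈0.19 bits for the eight other polyadic gates (partial
encryption, "obfuscation"), and 0 for gates that depend on at most one
input.  The feedback misestimate is the attribution mismatch
``|TE_{Y→Z} − I(Z_t:Z_{t+1})|`` for gates that depend on both inputs, and 0
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import pandas as pd

from .info_theory import (
    JointTable,
    co_information,
    conditional_mutual_information,
    entropy,
    mutual_information,
)

__all__ = [
    "Gate",
    "GateAnalytics",
    "GATE_CATALOG",
    "enumerate_gates",
    "gate_key",
    "gate_label",
    "classify_gate",
    "analytic_joint",
    "gate_analytics",
    "table1",
]

TruthTable = tuple[int, int, int, int]

# gate categories
CONSTANT = "constant"
DYADIC = "dyadic"
POLYADIC = "polyadic"
CRYPTOGRAPHIC = "cryptographic"


@dataclass(frozen=True)
class Gate:
    """A wired 2-input/1-output deterministic logic gate.

    ``table`` gives the output for input states (00, 01, 10, 11) of
    ``(inputs[0], inputs[1])``.  ``inputs`` may include ``output`` — that
    makes the gate a feedback gate.
    """

    inputs: tuple[int, int]
    output: int
    table: TruthTable

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "table", tuple(self.table))
        if len(self.inputs) != 2:
            raise ValueError("a gate has exactly two inputs")
        if len(self.table) != 4 or any(b not in (0, 1) for b in self.table):
            raise ValueError("truth table must be 4 binary entries")

    @property
    def is_feedback(self) -> bool:
        return self.output in self.inputs

    def __call__(self, a: int, b: int) -> int:
        return self.table[2 * a + b]


@dataclass(frozen=True)
class GateSpec:
    """Catalog entry: a canonical truth table with its name."""

    key: str        # unique (e.g. "AND-NOT-XY")
    label: str      # printed family name (e.g. "AND-NOT")
    table: TruthTable


# Row order of the canonical table; duplicated family labels (AND-NOT,
# COPY, NOT, OR-NOT) are disambiguated by the key suffix.
GATE_CATALOG: tuple[GateSpec, ...] = (
    GateSpec("ZERO", "ZERO", (0, 0, 0, 0)),
    GateSpec("AND", "AND", (0, 0, 0, 1)),
    GateSpec("AND-NOT-XY", "AND-NOT", (0, 0, 1, 0)),   # X AND (NOT Y)
    GateSpec("AND-NOT-YX", "AND-NOT", (0, 1, 0, 0)),   # (NOT X) AND Y
    GateSpec("NOR", "NOR", (1, 0, 0, 0)),
    GateSpec("COPY-X", "COPY", (0, 0, 1, 1)),
    GateSpec("COPY-Y", "COPY", (0, 1, 0, 1)),
    GateSpec("XOR", "XOR", (0, 1, 1, 0)),
    GateSpec("XNOR", "XNOR", (1, 0, 0, 1)),
    GateSpec("NOT-Y", "NOT", (1, 0, 1, 0)),
    GateSpec("NOT-X", "NOT", (1, 1, 0, 0)),
    GateSpec("OR", "OR", (0, 1, 1, 1)),
    GateSpec("OR-NOT-XY", "OR-NOT", (1, 0, 1, 1)),     # X OR (NOT Y)
    GateSpec("OR-NOT-YX", "OR-NOT", (1, 1, 0, 1)),     # (NOT X) OR Y
    GateSpec("NAND", "NAND", (1, 1, 1, 0)),
    GateSpec("ONE", "ONE", (1, 1, 1, 1)),
)

_BY_TABLE = {spec.table: spec for spec in GATE_CATALOG}


def enumerate_gates() -> list[GateSpec]:
    """The 16 canonical 2-to-1 gates, in catalog row order."""
    return list(GATE_CATALOG)


def gate_key(table: TruthTable) -> str:
    return _BY_TABLE[tuple(table)].key


def gate_label(table: TruthTable) -> str:
    return _BY_TABLE[tuple(table)].label


def classify_gate(table: TruthTable) -> str:
    """Classify by input dependence: constant / dyadic / polyadic / cryptographic."""
    t = tuple(table)
    dep_x = t[0] != t[2] or t[1] != t[3]
    dep_y = t[0] != t[1] or t[2] != t[3]
    if not dep_x and not dep_y:
        return CONSTANT
    if dep_x != dep_y:
        return DYADIC
    if t in ((0, 1, 1, 0), (1, 0, 0, 1)):
        return CRYPTOGRAPHIC
    return POLYADIC


def analytic_joint(table: TruthTable, wiring: str) -> JointTable:
    """Exact joint distribution induced by a gate under uniform inputs.

    ``wiring="feedforward"``: variables (Xt, Yt, Zt, Zt1) with X, Y, Zt iid
    uniform and Zt1 = f(Xt, Yt).  ``wiring="feedback"``: variables
    (Yt, Zt, Zt1) with Yt, Zt iid uniform and Zt1 = f(Yt, Zt).
    """
    t = tuple(table)
    if wiring == "feedforward":
        probs = {}
        for x in (0, 1):
            for y in (0, 1):
                for z in (0, 1):
                    probs[(x, y, z, t[2 * x + y])] = (
                        probs.get((x, y, z, t[2 * x + y]), 0.0) + 0.125
                    )
        return JointTable(("Xt", "Yt", "Zt", "Zt1"), probs)
    if wiring == "feedback":
        probs = {}
        for y in (0, 1):
            for z in (0, 1):
                probs[(y, z, t[2 * y + z])] = probs.get((y, z, t[2 * y + z]), 0.0) + 0.25
        return JointTable(("Yt", "Zt", "Zt1"), probs)
    raise ValueError(f"unknown wiring {wiring!r}")


@dataclass(frozen=True)
class GateAnalytics:
    """Analytic information quantities of one gate (all in bits, full precision)."""

    key: str
    label: str
    table: TruthTable
    category: str
    h_out: float             # H(Z_{t+1}), uniform inputs
    te_x: float              # feedforward TE_{X→Z}
    te_y: float              # feedforward TE_{Y→Z}
    te_error_ff: float       # H − TE_X − TE_Y
    co_info: float           # I(X:Y:Z_{t+1}); −1 crypto, ≈−0.19 polyadic
    te_y_fb: float           # feedback TE_{Y→Z}
    processed_fb: float      # feedback I(Z_t:Z_{t+1})
    te_error_fb: float       # attribution mismatch, gated on polyadicity


def gate_analytics(table: TruthTable) -> GateAnalytics:
    """Compute the full analytic row for one truth table."""
    spec = _BY_TABLE.get(tuple(table))
    key = spec.key if spec else str(tuple(table))
    label = spec.label if spec else key
    category = classify_gate(table)

    jff = analytic_joint(table, "feedforward")
    h_out = entropy(jff, ("Zt1",))
    te_x = conditional_mutual_information(jff, ("Zt1",), ("Xt",), ("Zt",))
    te_y = conditional_mutual_information(jff, ("Zt1",), ("Yt",), ("Zt",))
    err_ff = h_out - te_x - te_y
    coinfo = co_information(jff, ("Xt",), ("Yt",), ("Zt1",))

    jfb = analytic_joint(table, "feedback")
    te_y_fb = conditional_mutual_information(jfb, ("Zt1",), ("Yt",), ("Zt",))
    proc_fb = mutual_information(jfb, ("Zt",), ("Zt1",))
    if category in (POLYADIC, CRYPTOGRAPHIC):
        err_fb = abs(te_y_fb - proc_fb)
    else:
        err_fb = 0.0

    return GateAnalytics(
        key=key,
        label=label,
        table=tuple(table),
        category=category,
        h_out=h_out,
        te_x=te_x,
        te_y=te_y,
        te_error_ff=err_ff,
        co_info=coinfo,
        te_y_fb=te_y_fb,
        processed_fb=proc_fb,
        te_error_fb=err_fb,
    )


def iter_analytics() -> Iterator[GateAnalytics]:
    for spec in GATE_CATALOG:
        yield gate_analytics(spec.table)


def table1(decimals: int = 2) -> pd.DataFrame:
    """The full 16-gate analytic table, rounded for reporting.

    Columns mirror the canonical presentation: output entropy, the two
    feedforward transfer entropies and their total misestimate, then the
    feedback-loop transfer entropy, processed information and misestimate.
    """
    rows = []
    for a in iter_analytics():
        rows.append(
            {
                "gate": a.label,
                "key": a.key,
                "truth_table": "".join(map(str, a.table)),
                "category": a.category,
                "H_out": round(a.h_out, decimals),
                "TE_X": round(a.te_x, decimals),
                "TE_Y": round(a.te_y, decimals),
                "TE_error_ff": round(a.te_error_ff, decimals),
                "TE_Y_fb": round(a.te_y_fb, decimals),
                "processed_fb": round(a.processed_fb, decimals),
                "TE_error_fb": round(a.te_error_fb, decimals),
            }
        )
    return pd.DataFrame(rows)
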