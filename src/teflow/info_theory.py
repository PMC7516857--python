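"""Shannon information measures over discrete binary variables.

Everything in this package ultimately reduces to entropies of small joint
probability tables: analytic tables built from gate logic, and empirical
(plug-in) tables counted from recordings of behaving circuits.  All
quantities are in bits (log base 2) and history lengths are fixed at one
step, i.e. transfer entropy is ``I(Y_{t+1} : X_t | Y_t)``.

Conventions
-----------
* ``0 * log 0 = 0``.
* Mutual information and conditional mutual information are clamped to zero
  when floating point noise produces a tiny negative value; co-information
  is *not* clamped (negative co-information is the signature of synergy /
  encryption and is meaningful).
* Probabilities are plug-in (maximum likelihood) estimates from counts; no
  bias correction is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "JointTable",
    "TransitionDataset",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "co_information",
    "empirical_joint",
    "transfer_entropy",
    "conditional_transfer_entropy",
    "processed_information",
    "decomposition_residual",
    "random_joint_table",
]

_CLAMP = 1e-12


@dataclass(frozen=True)
class JointTable:
    """Joint probability distribution over named binary variables.

    Parameters
    ----------
    variables:
        Ordered variable names.
    probabilities:
        Mapping from full joint state tuples (entries in {0, 1}, one per
        variable) to probability.  States omitted from the mapping have
        probability zero.
    """

    variables: tuple[str, ...]
    probabilities: Mapping[tuple[int, ...], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        probs = dict(self.probabilities)
        total = 0.0
        for state, p in probs.items():
            if len(state) != len(self.variables):
                raise ValueError(
                    f"state {state} has arity {len(state)}, expected {len(self.variables)}"
                )
            if any(v not in (0, 1) for v in state):
                raise ValueError(f"state {state} has non-binary entries")
            if p < -_CLAMP:
                raise ValueError(f"negative probability {p} for state {state}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, expected 1")
        object.__setattr__(self, "probabilities", probs)

    def _indices(self, names: Sequence[str]) -> list[int]:
        idx = []
        for name in names:
            if name not in self.variables:
                raise KeyError(f"unknown variable {name!r}; have {self.variables}")
            idx.append(self.variables.index(name))
        return idx

    def marginal(self, names: Sequence[str]) -> "JointTable":
        """Marginal distribution over ``names`` (order preserved as given)."""
        idx = self._indices(names)
        out: dict[tuple[int, ...], float] = {}
        for state, p in self.probabilities.items():
            key = tuple(state[i] for i in idx)
            out[key] = out.get(key, 0.0) + p
        return JointTable(tuple(names), out)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "variables": list(self.variables),
            "probabilities": {
                "".join(map(str, state)): p for state, p in self.probabilities.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "JointTable":
        payload = json.loads(text)
        probs = {
            tuple(int(c) for c in key): p
            for key, p in payload["probabilities"].items()
        }
        return cls(tuple(payload["variables"]), probs)


@dataclass
class TransitionDataset:
    """Per-trial sequences of N-bit states from which transitions are counted.

    Transition pairs are formed only within a trial; the reset between
    trials is never counted as a transition.
    """

    trials: list[np.ndarray]
    n_neurons: int

    def __post_init__(self) -> None:
        checked = []
        for arr in self.trials:
            arr = np.asarray(arr, dtype=np.uint8)
            if arr.ndim != 2 or arr.shape[1] != self.n_neurons:
                raise ValueError(
                    f"trial has shape {arr.shape}, expected (T, {self.n_neurons})"
                )
            if arr.max(initial=0) > 1:
                raise ValueError("state entries must be in {0, 1}")
            checked.append(arr)
        self.trials = checked

    @property
    def n_snapshots(self) -> int:
        return sum(len(t) for t in self.trials)

    @property
    def n_transitions(self) -> int:
        return sum(max(len(t) - 1, 0) for t in self.trials)


def _h(probs: Iterable[float]) -> float:
    acc = 0.0
    for p in probs:
        if p > 0.0:
            acc -= p * math.log2(p)
    return acc


def entropy(joint: JointTable, names: Sequence[str] | None = None) -> float:
    """Shannon entropy (bits) of the marginal of ``joint`` on ``names``."""
    if names is None:
        names = joint.variables
    if len(names) == 0:
        raise ValueError("entropy requires a non-empty variable subset")
    marg = joint.marginal(names)
    return _h(marg.probabilities.values())


def conditional_entropy(joint: JointTable, a: Sequence[str], b: Sequence[str]) -> float:
    """H(A | B) = H(A, B) − H(B)."""
    if not b:
        return entropy(joint, a)
    return entropy(joint, tuple(a) + tuple(b)) - entropy(joint, b)


def _check_disjoint(*groups: Sequence[str]) -> None:
    seen: set[str] = set()
    for group in groups:
        for name in group:
            if name in seen:
                raise ValueError(f"variable {name!r} appears in more than one argument set")
            seen.add(name)


def mutual_information(joint: JointTable, a: Sequence[str], b: Sequence[str]) -> float:
    """I(A : B) = H(A) + H(B) − H(A, B), clamped at zero."""
    _check_disjoint(a, b)
    val = entropy(joint, a) + entropy(joint, b) - entropy(joint, tuple(a) + tuple(b))
    return max(val, 0.0)


def conditional_mutual_information(
    joint: JointTable, a: Sequence[str], b: Sequence[str], c: Sequence[str]
) -> float:
    """I(A : B | C) = H(A,C) + H(B,C) − H(A,B,C) − H(C), clamped at zero."""
    _check_disjoint(a, b, c)
    if not c:
        return mutual_information(joint, a, b)
    a, b, c = tuple(a), tuple(b), tuple(c)
    val = (
        entropy(joint, a + c)
        + entropy(joint, b + c)
        - entropy(joint, a + b + c)
        - entropy(joint, c)
    )
    return max(val, 0.0)


def co_information(
    joint: JointTable,
    a: Sequence[str],
    b: Sequence[str],
    c: Sequence[str],
    given: Sequence[str] = (),
) -> float:
    """Three-way co-information I(A : B : C | given) = I(A:B|given) − I(A:B|C,given).

    Symmetric under any permutation of ``a``, ``b``, ``c``.  May be negative:
    negative values signal synergy (the XOR one-time-pad gives −1).
    """
    _check_disjoint(a, b, c, given)
    a, b, c, given = tuple(a), tuple(b), tuple(c), tuple(given)
    # Unclamped expansion: clamping the two CMI terms separately would bias
    # the (legitimately negative) difference.
    def _i(x: tuple[str, ...], y: tuple[str, ...], z: tuple[str, ...]) -> float:
        if not z:
            return entropy(joint, x) + entropy(joint, y) - entropy(joint, x + y)
        return (
            entropy(joint, x + z)
            + entropy(joint, y + z)
            - entropy(joint, x + y + z)
            - entropy(joint, z)
        )

    return _i(a, b, given) - _i(a, b, c + given)


# ---------------------------------------------------------------------------
# Empirical (plug-in) estimates from recordings
# ---------------------------------------------------------------------------

def empirical_joint(
    ds: TransitionDataset, variables: Sequence[tuple[str, int, int]]
) -> JointTable:
    """Plug-in joint table over time-lagged neuron variables.

    ``variables`` is a sequence of ``(name, neuron, offset)`` with offset 0
    (time t) or 1 (time t+1); counts pool all within-trial transitions.
    """
    names = tuple(name for name, _, _ in variables)
    counts: dict[tuple[int, ...], int] = {}
    total = 0
    for arr in ds.trials:
        for t in range(len(arr) - 1):
            key = tuple(int(arr[t + off, neuron]) for _, neuron, off in variables)
            counts[key] = counts.get(key, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("dataset contains no transitions")
    return JointTable(names, {k: v / total for k, v in counts.items()})


def transfer_entropy(ds: TransitionDataset, src: int, dst: int) -> float:
    """TE(src → dst) = I(dst_{t+1} : src_t | dst_t), history length 1."""
    if src == dst:
        raise ValueError(
            "src == dst: the transfer entropy of a process to itself is the "
            "processed information; use processed_information() instead"
        )
    joint = empirical_joint(
        ds, [("dst1", dst, 1), ("src0", src, 0), ("dst0", dst, 0)]
    )
    return conditional_mutual_information(joint, ("dst1",), ("src0",), ("dst0",))


def conditional_transfer_entropy(
    ds: TransitionDataset, src: int, dst: int, cond: int
) -> float:
    """TE(src → dst | cond) = I(dst_{t+1} : src_t | dst_t, cond_t)."""
    if src == dst:
        raise ValueError("src == dst: use processed_information() instead")
    if cond in (src, dst):
        raise ValueError("cond must differ from src and dst")
    joint = empirical_joint(
        ds,
        [("dst1", dst, 1), ("src0", src, 0), ("dst0", dst, 0), ("cond0", cond, 0)],
    )
    return conditional_mutual_information(
        joint, ("dst1",), ("src0",), ("dst0", "cond0")
    )


def processed_information(ds: TransitionDataset, node: int) -> float:
    """I(node_t : node_{t+1}), the information a neuron carries about its own future."""
    joint = empirical_joint(ds, [("z0", node, 0), ("z1", node, 1)])
    return mutual_information(joint, ("z0",), ("z1",))


# ---------------------------------------------------------------------------
# Entropy decomposition identities
# ---------------------------------------------------------------------------

def decomposition_residual(joint: JointTable, mode: str) -> float:
    """Residual of an exact entropy-decomposition identity (should be ~0).

    Modes
    -----
    ``"feedforward"``
        H(Z1) = TE_{Y→Z|X} + TE_{X→Z|Y} + I(X:Y:Z1|Z); valid when Z1 is a
        deterministic function of (X, Y) and independent of Zt.  Requires
        variables ``Xt, Yt, Zt, Zt1``.
    ``"feedback"``
        H(Z1) = TE_{Y→Z} + I(Zt:Z1); valid when Z1 is a deterministic
        function of (Y, Z).  Requires variables ``Yt, Zt, Zt1``.
    ``"general"``
        H(Z1) = TE_{Y→Z|X} + TE_{X→Z|Y} + I(X:Y:Z1|Z) + I(Zt:Z1)
        + H(Z1|X,Y,Z); an identity for *any* joint over ``Xt, Yt, Zt, Zt1``.
    """
    if mode == "feedforward":
        _require(joint, ("Xt", "Yt", "Zt", "Zt1"))
        rhs = (
            conditional_mutual_information(joint, ("Yt",), ("Zt1",), ("Zt", "Xt"))
            + conditional_mutual_information(joint, ("Xt",), ("Zt1",), ("Zt", "Yt"))
            + co_information(joint, ("Xt",), ("Yt",), ("Zt1",), given=("Zt",))
        )
    elif mode == "feedback":
        _require(joint, ("Yt", "Zt", "Zt1"))
        rhs = conditional_mutual_information(
            joint, ("Yt",), ("Zt1",), ("Zt",)
        ) + mutual_information(joint, ("Zt",), ("Zt1",))
    elif mode == "general":
        _require(joint, ("Xt", "Yt", "Zt", "Zt1"))
        rhs = (
            conditional_mutual_information(joint, ("Yt",), ("Zt1",), ("Zt", "Xt"))
            + conditional_mutual_information(joint, ("Xt",), ("Zt1",), ("Zt", "Yt"))
            + co_information(joint, ("Xt",), ("Yt",), ("Zt1",), given=("Zt",))
            + mutual_information(joint, ("Zt",), ("Zt1",))
            + conditional_entropy(joint, ("Zt1",), ("Xt", "Yt", "Zt"))
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return entropy(joint, ("Zt1",)) - rhs


def _require(joint: JointTable, names: tuple[str, ...]) -> None:
    missing = [n for n in names if n not in joint.variables]
    if missing:
        raise ValueError(f"joint is missing required variables {missing}")


def random_joint_table(
    rng: np.random.Generator, variables: Sequence[str]
) -> JointTable:
    """Random dense joint table over binary ``variables`` (for property tests)."""
    k = len(variables)
    weights = rng.random(2**k) + 1e-6
    weights /= weights.sum()
    states = [tuple((i >> j) & 1 for j in range(k)) for i in range(2**k)]
    return JointTable(tuple(variables), dict(zip(states, weights.tolist())))
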