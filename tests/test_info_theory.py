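"""Information measures: analytic examples, plug-in estimates, identities."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teflow.gate_catalog import GATE_CATALOG, analytic_joint
from teflow.info_theory import (
    JointTable,
    TransitionDataset,
    co_information,
    conditional_mutual_information,
    conditional_transfer_entropy,
    decomposition_residual,
    entropy,
    mutual_information,
    processed_information,
    random_joint_table,
    transfer_entropy,
)

AND = (0, 0, 0, 1)
XOR = (0, 1, 1, 0)


def _bern(p: float) -> JointTable:
    return JointTable(("Z",), {(1,): p, (0,): 1 - p})


def uniform_gate_joint(table) -> JointTable:
    """(X, Y, Z) with X, Y iid uniform and Z = f(X, Y) (time-independent)."""
    probs = {}
    for x in (0, 1):
        for y in (0, 1):
            key = (x, y, table[2 * x + y])
            probs[key] = probs.get(key, 0.0) + 0.25
    return JointTable(("X", "Y", "Z"), probs)


def gate_process_dataset(table, feedback: bool) -> TransitionDataset:
    """Exhaustively sampled one-gate process as 2-step trials on 3 neurons.

    Feedforward: Z_{t+1} = f(X_t, Y_t) over all 8 (x, y, z) combinations;
    feedback: Z_{t+1} = f(Y_t, Z_t) over all 4 (y, z) combinations.
    Neurons are (X, Y, Z) = (0, 1, 2).
    """
    trials = []
    if feedback:
        for y in (0, 1):
            for z in (0, 1):
                trials.append([[0, y, z], [0, y, table[2 * y + z]]])
    else:
        for x in (0, 1):
            for y in (0, 1):
                for z in (0, 1):
                    trials.append([[x, y, z], [x, y, table[2 * x + y]]])
    return TransitionDataset([np.array(t, dtype=np.uint8) for t in trials], n_neurons=3)


class TestJointTable:
    def test_validation_rejects_bad_tables(self):
        with pytest.raises(ValueError, match="sum"):
            JointTable(("A",), {(0,): 0.4, (1,): 0.4})
        with pytest.raises(ValueError, match="arity"):
            JointTable(("A", "B"), {(0,): 1.0})
        with pytest.raises(ValueError, match="non-binary"):
            JointTable(("A",), {(2,): 1.0})

    def test_json_round_trip(self):
        j = uniform_gate_joint(AND)
        back = JointTable.from_json(j.to_json())
        assert back.variables == j.variables
        assert back.probabilities == pytest.approx(j.probabilities)

    def test_unknown_variable_named_in_error(self):
        with pytest.raises(KeyError, match="Q"):
            entropy(_bern(0.5), ("Q",))


class TestEntropyAndMutualInformation:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 1.0), (0.25, 0.8112781244591328), (1.0, 0.0), (0.0, 0.0)],
    )
    def test_bernoulli_entropy(self, p, expected):
        assert entropy(_bern(p)) == pytest.approx(expected, abs=1e-12)

    def test_copy_and_xor_mutual_information(self):
        copy = JointTable(("X", "Z"), {(0, 0): 0.5, (1, 1): 0.5})
        assert mutual_information(copy, ("X",), ("Z",)) == pytest.approx(1.0)
        xor = uniform_gate_joint(XOR)
        # each input alone shares nothing with the output: the one-time pad
        assert mutual_information(xor, ("X",), ("Z",)) == pytest.approx(0.0, abs=1e-12)
        assert mutual_information(xor, ("Y",), ("Z",)) == pytest.approx(0.0, abs=1e-12)
        a = uniform_gate_joint(AND)
        assert mutual_information(a, ("X",), ("Z",)) == pytest.approx(0.31127812, abs=1e-8)

    def test_overlapping_sets_rejected(self):
        j = uniform_gate_joint(AND)
        with pytest.raises(ValueError, match="more than one"):
            mutual_information(j, ("X",), ("X", "Z"))
        with pytest.raises(ValueError, match="more than one"):
            conditional_mutual_information(j, ("X",), ("Z",), ("X",))


class TestCoInformation:
    def test_xor_is_perfect_encryption(self):
        j = uniform_gate_joint(XOR)
        assert co_information(j, ("X",), ("Y",), ("Z",)) == pytest.approx(-1.0, abs=1e-12)

    def test_and_obfuscates(self):
        j = uniform_gate_joint(AND)
        assert co_information(j, ("X",), ("Y",), ("Z",)) == pytest.approx(-0.19, abs=0.005)

    def test_independent_copy_has_zero_coinfo(self):
        probs = {}
        for x in (0, 1):
            for y in (0, 1):
                probs[(x, y, x)] = 0.25  # Z = X, Y independent
        j = JointTable(("X", "Y", "Z"), probs)
        assert co_information(j, ("X",), ("Y",), ("Z",)) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        j = random_joint_table(rng, ("A", "B", "C"))
        vals = {
            co_information(j, (a,), (b,), (c,))
            for a, b, c in (
                ("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B"),
                ("B", "A", "C"), ("A", "C", "B"), ("C", "B", "A"),
            )
        }
        assert max(vals) - min(vals) < 1e-9


class TestTransferEntropy:
    def test_xor_feedback_overestimates_single_source(self):
        ds = gate_process_dataset(XOR, feedback=True)
        assert transfer_entropy(ds, 1, 2) == pytest.approx(1.0, abs=1e-12)
        # ... while the processed information vanishes
        assert processed_information(ds, 2) == pytest.approx(0.0, abs=1e-12)

    def test_and_feedback(self):
        ds = gate_process_dataset(AND, feedback=True)
        assert transfer_entropy(ds, 1, 2) == pytest.approx(0.5, abs=1e-12)
        assert processed_information(ds, 2) == pytest.approx(0.31127812, abs=1e-8)

    def test_constant_destination_has_zero_te(self):
        trials = [np.array([[0, 1, 0], [0, 0, 0], [0, 1, 0]], dtype=np.uint8)]
        ds = TransitionDataset(trials, n_neurons=3)
        assert transfer_entropy(ds, 1, 2) == 0.0

    def test_self_pair_and_empty_dataset_rejected(self):
        ds = gate_process_dataset(AND, feedback=True)
        with pytest.raises(ValueError, match="processed_information"):
            transfer_entropy(ds, 2, 2)
        with pytest.raises(ValueError, match="no transitions"):
            transfer_entropy(TransitionDataset([], n_neurons=3), 0, 1)

    def test_self_copy_processes_one_bit(self):
        trials = [
            np.array([[0, 0, z], [0, 0, z]], dtype=np.uint8) for z in (0, 1)
        ]
        assert processed_information(
            TransitionDataset(trials, n_neurons=3), 2
        ) == pytest.approx(1.0)

    def test_conditional_te_feedforward_xor(self):
        ds = gate_process_dataset(XOR, feedback=False)
        # conditioning on the other input reveals the hidden flow
        assert conditional_transfer_entropy(ds, 1, 2, 0) == pytest.approx(1.0, abs=1e-12)
        # pure relay: Z_{t+1} = X_t leaves nothing for Y
        copy_x = (0, 0, 1, 1)
        ds2 = gate_process_dataset(copy_x, feedback=False)
        assert conditional_transfer_entropy(ds2, 1, 2, 0) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="cond"):
            conditional_transfer_entropy(ds, 0, 2, 0)

    def test_and_output_entropy_decomposes_over_conditional_tes(self):
        ds = gate_process_dataset(AND, feedback=False)
        joint = analytic_joint(AND, "feedforward")
        total = (
            conditional_transfer_entropy(ds, 1, 2, 0)
            + conditional_transfer_entropy(ds, 0, 2, 1)
            + co_information(joint, ("Xt",), ("Yt",), ("Zt1",), given=("Zt",))
        )
        assert total == pytest.approx(entropy(joint, ("Zt1",)), abs=1e-9)
        assert total == pytest.approx(0.8112781244591328, abs=1e-9)

    def test_trials_never_concatenated(self):
        # two constant trials whose concatenation would fake a transition
        trials = [
            np.array([[0, 0, 0], [0, 0, 0]], dtype=np.uint8),
            np.array([[0, 1, 1], [0, 1, 1]], dtype=np.uint8),
        ]
        ds = TransitionDataset(trials, n_neurons=3)
        assert ds.n_transitions == 2
        assert transfer_entropy(ds, 1, 2) == 0.0  # within-trial Z never changes


class TestDecompositionIdentities:
    @pytest.mark.parametrize("spec", GATE_CATALOG, ids=lambda s: s.key)
    def test_gate_joints_satisfy_identities(self, spec):
        assert abs(decomposition_residual(analytic_joint(spec.table, "feedforward"), "feedforward")) < 1e-9
        assert abs(decomposition_residual(analytic_joint(spec.table, "feedback"), "feedback")) < 1e-9
        assert abs(decomposition_residual(analytic_joint(spec.table, "feedforward"), "general")) < 1e-9

    @settings(derandomize=True, max_examples=120)
    @given(st.integers(0, 2**31 - 1))
    def test_general_identity_on_arbitrary_joints(self, seed):
        rng = np.random.default_rng(seed)
        joint = random_joint_table(rng, ("Xt", "Yt", "Zt", "Zt1"))
        assert abs(decomposition_residual(joint, "general")) < 1e-9

    @settings(derandomize=True, max_examples=120)
    @given(st.integers(0, 2**31 - 1))
    def test_feedforward_identity_on_random_deterministic_joints(self, seed):
        rng = np.random.default_rng(seed)
        # random p(x, y) x p(z), deterministic random f: the preconditions
        pxy = rng.random(4) + 1e-6
        pxy /= pxy.sum()
        pz = rng.random(2) + 1e-6
        pz /= pz.sum()
        f = rng.integers(0, 2, size=4)
        probs = {}
        for i, (x, y) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            for z in (0, 1):
                key = (x, y, z, int(f[i]))
                probs[key] = probs.get(key, 0.0) + pxy[i] * pz[z]
        joint = JointTable(("Xt", "Yt", "Zt", "Zt1"), probs)
        assert abs(decomposition_residual(joint, "feedforward")) < 1e-9

    @settings(derandomize=True, max_examples=120)
    @given(st.integers(0, 2**31 - 1))
    def test_feedback_identity_on_random_deterministic_joints(self, seed):
        rng = np.random.default_rng(seed)
        pyz = rng.random(4) + 1e-6
        pyz /= pyz.sum()
        f = rng.integers(0, 2, size=4)
        probs = {}
        for i, (y, z) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            key = (y, z, int(f[i]))
            probs[key] = probs.get(key, 0.0) + pyz[i]
        joint = JointTable(("Yt", "Zt", "Zt1"), probs)
        assert abs(decomposition_residual(joint, "feedback")) < 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_te_chain_rule(self, seed):
        # TE_{Y->Z} = TE_{Y->Z|X} + I(X:Y:Z1|Z) on arbitrary joints
        rng = np.random.default_rng(seed)
        j = random_joint_table(rng, ("Xt", "Yt", "Zt", "Zt1"))
        te_y = conditional_mutual_information(j, ("Yt",), ("Zt1",), ("Zt",))
        cte_y = conditional_mutual_information(j, ("Yt",), ("Zt1",), ("Zt", "Xt"))
        coi = co_information(j, ("Xt",), ("Yt",), ("Zt1",), given=("Zt",))
        assert te_y == pytest.approx(cte_y + coi, abs=1e-9)

    def test_processed_information_feedback_split(self):
        # I(Z:Z1) = I(Z:Z1|Y) + I(Z1:Z:Y); for XOR the parts are +1 and -1
        joint = analytic_joint(XOR, "feedback")
        given_y = conditional_mutual_information(joint, ("Zt",), ("Zt1",), ("Yt",))
        coi = co_information(joint, ("Zt1",), ("Zt",), ("Yt",))
        assert given_y == pytest.approx(1.0, abs=1e-12)
        assert coi == pytest.approx(-1.0, abs=1e-12)
        assert mutual_information(joint, ("Zt",), ("Zt1",)) == pytest.approx(
            given_y + coi, abs=1e-12
        )


class TestEmpiricalMatchesAnalytic:
    @pytest.mark.parametrize("spec", GATE_CATALOG, ids=lambda s: s.key)
    def test_exhaustive_plugin_equals_analytic(self, spec):
        """A complete sample makes the plug-in estimator exact."""
        from teflow.gate_catalog import gate_analytics

        a = gate_analytics(spec.table)
        ff = gate_process_dataset(spec.table, feedback=False)
        assert transfer_entropy(ff, 0, 2) == pytest.approx(a.te_x, abs=1e-12)
        assert transfer_entropy(ff, 1, 2) == pytest.approx(a.te_y, abs=1e-12)
        fb = gate_process_dataset(spec.table, feedback=True)
        assert transfer_entropy(fb, 1, 2) == pytest.approx(a.te_y_fb, abs=1e-12)
        assert processed_information(fb, 2) == pytest.approx(a.processed_fb, abs=1e-12)
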