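"""Measurement assemblies, branches, reduction and assemblage construction."""

import json

import numpy as np
import pytest

import ststeer as st
from ststeer.assemblage import PAULI, QubitSpace2
from ststeer.dynamics import Operator, QuantumState


class TestPauliSet:
    def test_structure_and_projectors(self, pauli_set):
        assert pauli_set.n_settings == 3
        assert pauli_set.n_outcomes == 2
        for x in range(3):
            assert np.allclose(pauli_set.elements[x].sum(axis=0), np.eye(2))
            for a in range(2):
                F = pauli_set.elements[x, a]
                assert np.allclose(F @ F, F, atol=1e-12)  # rank-1 projector
                assert np.linalg.matrix_rank(F) == 1

    def test_plus_z_is_excited_projector(self, pauli_set):
        # outcome "+" of Z projects onto the excited state |e> (basis (g, e))
        assert np.allclose(pauli_set.elements[2, 0], np.diag([0.0, 1.0]))


class TestPostMeasurementBranches:
    def test_z_eigenstate_collapses_one_branch(self, pauli_set):
        space = st.build_state_space(3)
        rho = np.zeros((4, 4), dtype=complex)
        rho[1, 1] = 1.0  # |e1>
        branches = st.post_measurement_branches(QuantumState(space, rho), pauli_set, 1)
        # setting Z (index 2): + has the full weight, - none
        assert np.trace(branches[2, 0]).real == pytest.approx(1.0, abs=1e-12)
        assert np.trace(branches[2, 1]).real == pytest.approx(0.0, abs=1e-12)

    def test_mixed_site_gives_pure_superposition_branches(self, pauli_set):
        # FMO-style initial state: maximally mixed at the measured site
        space = st.build_state_space(7, include_reaction_center=True)
        d = space.dimension
        rho = np.zeros((d, d), dtype=complex)
        rho[0, 0] = 0.5
        i6 = space.site_index(6)
        rho[i6, i6] = 0.5
        branches = st.post_measurement_branches(QuantumState(space, rho), pauli_set, 6)
        for a, sign in ((0, 1.0), (1, -1.0)):
            b = branches[0, a]  # X setting
            assert np.trace(b).real == pytest.approx(0.5, abs=1e-12)
            v = np.zeros(d, dtype=complex)
            v[0] = 1 / np.sqrt(2)
            v[i6] = sign / np.sqrt(2)
            assert np.abs(b - 0.5 * np.outer(v, v.conj())).max() < 1e-12

    def test_identity_povm_returns_the_state(self):
        space = st.build_state_space(2)
        rho = np.diag([0.2, 0.3, 0.5]).astype(complex)
        trivial = st.MeasurementAssembly(np.eye(2, dtype=complex).reshape(1, 1, 2, 2))
        branches = st.post_measurement_branches(QuantumState(space, rho), trivial, 1)
        assert np.allclose(branches[0, 0], rho)


class TestReduceToSiteQubit:
    def test_excited_and_ground_projections(self):
        space = st.build_state_space(3)
        rho = np.zeros((4, 4), dtype=complex)
        rho[3, 3] = 1.0  # |e3>
        red = st.reduce_to_site_qubit(QuantumState(space, rho), 3)
        assert np.allclose(red.matrix, np.diag([0.0, 1.0]))
        red2 = st.reduce_to_site_qubit(QuantumState(space, rho), 2)
        assert np.allclose(red2.matrix, np.diag([1.0, 0.0]))

    def test_vacuum_site_superposition_reduces_to_pure_plus(self):
        # independent oracle: partial trace in the full 2**3 embedding
        from conftest import full_basis_index, sector_to_full

        space = st.build_state_space(3)
        v = np.zeros(4, dtype=complex)
        v[0] = v[3] = 1 / np.sqrt(2)  # (|vac> + |e3>)/sqrt(2)
        rho = np.outer(v, v.conj())
        red = st.reduce_to_site_qubit(QuantumState(space, rho), 3).matrix

        rho_full = sector_to_full(rho, space)
        # trace out qubits 1 and 2 (site 3 is the least significant tensor factor)
        ref = np.einsum("xayb->ab", rho_full.reshape(4, 2, 4, 2))
        assert np.abs(red - ref).max() < 1e-12
        assert np.allclose(red, 0.5 * np.array([[1, 1], [1, 1]]))


class TestAssemblageConstruction:
    def test_chain_at_time_zero_targets_ground(self):
        sc = st.three_qubit_chain_scenario(gamma=0.2)
        asm = st.assemblage_at(sc, 0.0)
        probs = asm.probabilities()
        for x in range(3):
            for a in range(2):
                expected = probs[x, a] * np.diag([1.0, 0.0])
                assert np.abs(asm.members[x, a] - expected).max() < 1e-10

    def test_werner_epr_reduction_closed_form(self):
        # identity channel steering of a Werner state: (I + a p sigma_w^T)/4
        p = 0.73
        asm = st.werner_assemblage(p)
        for x, w in enumerate("XYZ"):
            for a, sign in ((0, 1.0), (1, -1.0)):
                expected = (np.eye(2) + sign * p * PAULI[w].T) / 4.0
                assert np.abs(asm.members[x, a] - expected).max() < 1e-12

    def test_discard_channel_factorizes(self):
        rho_fixed = np.array([[0.7, 0.1], [0.1, 0.3]], dtype=complex)
        sc = st.discard_channel_scenario(rho_fixed)
        asm = st.assemblage_at(sc, 2.5)
        probs = asm.probabilities()
        for x in range(3):
            for a in range(2):
                assert np.abs(asm.members[x, a] - probs[x, a] * rho_fixed).max() < 1e-12

    def test_probability_conservation_along_chain_scan(self):
        sc = st.three_qubit_chain_scenario(gamma=0.5)
        for asm in st.assemblage_trajectory(sc, np.linspace(0, 4, 5)):
            sums = asm.probabilities().sum(axis=1)
            assert np.abs(sums - 1.0).max() < 1e-8

    def test_linearity_in_the_initial_state(self, pauli_set):
        sc = st.three_qubit_chain_scenario(gamma=0.4)
        space = sc.space
        rng = np.random.default_rng(8)
        # two sector-supported initial states over {vac, e1}
        states = []
        for _ in range(2):
            v = np.zeros(4, dtype=complex)
            amp = rng.normal(size=2) + 1j * rng.normal(size=2)
            amp /= np.linalg.norm(amp)
            v[0], v[1] = amp
            states.append(np.outer(v, v.conj()))
        q = 0.35
        mix = q * states[0] + (1 - q) * states[1]
        asms = []
        for rho in (states[0], states[1], mix):
            scenario = st.Scenario(
                rho0=QuantumState(space, rho),
                measured_site=1,
                target_site=3,
                assembly=pauli_set,
                channel=sc.channel,
            )
            asms.append(st.assemblage_at(scenario, 1.3).members)
        assert np.abs(q * asms[0] + (1 - q) * asms[1] - asms[2]).max() < 1e-8


class TestTemporalReduction:
    def test_single_system_reproduces_temporal_assemblage(self, pauli_set):
        # one qubit measured at t=0 then evolved: the spatio-temporal pipeline
        # must reproduce p(a|x) * Lambda_t[conditional state] member for member.
        space = st.build_state_space(1)
        H = 0.9 * np.array([[0, 1], [1, 0]], dtype=complex)
        model = st.LindbladModel(
            Operator(space, H),
            [(0.15, st.embed_site_operator("sigma_z", 1, space))],
        )
        rho0 = np.array([[0.6, 0.2 - 0.1j], [0.2 + 0.1j, 0.4]], dtype=complex)
        scenario = st.Scenario(
            rho0=QuantumState(space, rho0),
            measured_site=1,
            target_site=1,
            assembly=pauli_set,
            channel=model,
            temporal=True,
        )
        t = 1.1
        asm = st.assemblage_at(scenario, t)

        for x in range(3):
            for a in range(2):
                F = pauli_set.elements[x, a]
                p = float(np.real(np.trace(F @ rho0)))
                branch = F @ rho0 @ F  # projective collapse
                evolved = st.evolve(
                    QuantumState(space, branch, expected_trace=None), model, [0.0, t]
                )[-1].matrix
                assert np.abs(asm.members[x, a] - evolved).max() < 1e-10
                assert asm.probabilities()[x, a] == pytest.approx(p, abs=1e-10)


class TestValidation:
    def test_epr_reduction_is_non_signalling(self):
        rep = st.validate_assemblage(st.werner_assemblage(0.9))
        assert rep.non_signalling
        assert rep.trace_sums_ok
        assert rep.members_psd

    def test_chain_assemblage_signals_through_the_channel(self):
        sc = st.three_qubit_chain_scenario(gamma=0.0)
        asm = st.assemblage_at(sc, 1.0)
        rep = st.validate_assemblage(asm)
        assert not rep.non_signalling  # measurement disturbance propagates
        assert rep.trace_sums_ok

    def test_discard_channel_is_non_signalling(self):
        asm = st.assemblage_at(st.discard_channel_scenario(), 1.0)
        assert st.validate_assemblage(asm).non_signalling


class TestSerialization:
    def test_json_round_trip_preserves_members(self, tmp_path):
        sc = st.three_qubit_chain_scenario(gamma=0.1)
        asm = st.assemblage_at(sc, 0.7)
        payload = json.dumps(asm.to_json())
        back = st.Assemblage.from_json(json.loads(payload))
        assert np.array_equal(back.members, asm.members)
        assert back.time == asm.time

    def test_invalid_assemblage_rejected_on_load(self):
        bad = st.werner_assemblage(0.5)
        payload = bad.to_json()
        payload["members"][0][0][0][0]["re"] = -5.0  # wildly negative population
        with pytest.raises(ValueError):
            st.Assemblage.from_json(payload)
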