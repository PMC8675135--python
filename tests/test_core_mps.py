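"""Tensor algebra of the MPS/MPO layer, checked against dense linear algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpssi.core_mps import (
    MPS,
    DenseState,
    add,
    apply_mpo,
    compress,
    inner,
    mps_from_dense,
    mps_to_dense,
    scale,
    spin_squared_expectation,
)
from mpssi.exceptions import MalformedStateError, ResourceLimitError, ShapeError
from mpssi.operators import excitation_mpo, identity_mpo
from mpssi.oracle import dense_excitation, dense_spin_squared

from conftest import random_dense_state


class TestDenseRoundTrip:
    @pytest.mark.parametrize("L", [2, 3, 4, 5])
    def test_round_trip_is_identity_at_zero_tol(self, rng, L):
        st_ = random_dense_state(rng, L)
        back = mps_to_dense(mps_from_dense(st_, 0.0))
        assert np.abs(back.amplitudes - st_.amplitudes).max() < 1e-12

    def test_product_state_has_unit_bond_dims(self):
        # |updown, 0> on two orbitals: a single determinant factorizes trivially
        v = np.zeros(16)
        v[DenseState.occupations_to_index([3, 0])] = 1.0
        psi = mps_from_dense(DenseState(v), 0.0)
        assert all(b == 1 for b in psi.bond_dims)

    def test_zero_vector_rejected(self):
        with pytest.raises(MalformedStateError):
            mps_from_dense(DenseState(np.zeros(16)), 0.0)

    def test_non_power_of_four_length_rejected(self):
        with pytest.raises(MalformedStateError):
            DenseState(np.ones(10))

    def test_log_scale_multiplies_amplitudes(self):
        v = np.zeros(16)
        v[0] = 1.0
        psi = mps_from_dense(DenseState(v), 0.0)
        psi.log_scale = np.log(2.0)
        assert np.allclose(mps_to_dense(psi).amplitudes, 2.0 * v)

    def test_dense_cap_enforced(self, rng):
        psi = mps_from_dense(random_dense_state(rng, 3), 0.0)
        with pytest.raises(ResourceLimitError):
            mps_to_dense(psi, cap=2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_round_trip_property(self, data):
        L = data.draw(st.integers(2, 4))
        seed = data.draw(st.integers(0, 2**20))
        v = np.random.default_rng(seed).standard_normal(4**L)
        v /= np.linalg.norm(v)
        back = mps_to_dense(mps_from_dense(DenseState(v), 0.0))
        assert np.abs(back.amplitudes - v).max() < 1e-12


class TestInner:
    def test_normalized_self_overlap(self, rng):
        psi = mps_from_dense(random_dense_state(rng, 3), 0.0)
        assert inner(psi, psi) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("complex_", [False, True])
    def test_matches_dense_dot(self, rng, complex_):
        a = random_dense_state(rng, 4, complex_)
        b = random_dense_state(rng, 4, complex_)
        val = inner(mps_from_dense(a, 0.0), mps_from_dense(b, 0.0))
        assert abs(val - np.vdot(a.amplitudes, b.amplitudes)) < 1e-12

    def test_conjugate_symmetry(self, rng):
        a = mps_from_dense(random_dense_state(rng, 3, True), 0.0)
        b = mps_from_dense(random_dense_state(rng, 3, True), 0.0)
        assert inner(a, b) == pytest.approx(np.conj(inner(b, a)), abs=1e-14)

    def test_length_mismatch(self, rng):
        a = mps_from_dense(random_dense_state(rng, 2), 0.0)
        b = mps_from_dense(random_dense_state(rng, 3), 0.0)
        with pytest.raises(ShapeError):
            inner(a, b)


class TestCompress:
    def test_no_truncation_preserves_state(self, rng):
        st_ = random_dense_state(rng, 4)
        psi = mps_from_dense(st_, 0.0)
        out, w = compress(psi, m=max(psi.bond_dims), tol=0.0)
        assert w == 0.0
        assert np.abs(mps_to_dense(out).amplitudes - st_.amplitudes).max() < 1e-12

    def test_schmidt_example_discarded_weight(self):
        # rank-2 two-site state with Schmidt coefficients (0.8, 0.6):
        # keeping one state discards 0.6**2 = 0.36
        v = np.zeros(16)
        v[DenseState.occupations_to_index([1, 2])] = 0.8
        v[DenseState.occupations_to_index([2, 1])] = 0.6
        psi = mps_from_dense(DenseState(v), 0.0)
        out, w = compress(psi, m=1)
        assert w == pytest.approx(0.36, abs=1e-12)
        assert out.norm_squared() == pytest.approx(0.64, abs=1e-12)

    def test_discarded_weight_is_norm_loss(self, rng):
        psi = mps_from_dense(random_dense_state(rng, 5), 0.0)
        psi = scale(psi, 1.7)  # exercise the log_scale bookkeeping too
        n2 = psi.norm_squared()
        out, w = compress(psi, m=3)
        assert n2 - out.norm_squared() == pytest.approx(w, abs=1e-10)

    def test_idempotence_at_fixed_m(self, rng):
        psi = mps_from_dense(random_dense_state(rng, 4), 0.0)
        once, _ = compress(psi, m=2)
        twice, w2 = compress(once, m=2)
        assert w2 < 1e-24
        d1 = mps_to_dense(once).amplitudes
        d2 = mps_to_dense(twice).amplitudes
        assert np.abs(d1 - d2).max() < 1e-12

    def test_fidelity_non_decreasing_in_m(self, rng):
        st_ = random_dense_state(rng, 4)
        psi = mps_from_dense(st_, 0.0)
        fids = []
        for m in (1, 2, 3, 4, 8, 16):
            out, _ = compress(psi, m)
            ov = abs(inner(psi, out)) ** 2
            fids.append(ov / (psi.norm_squared() * out.norm_squared()))
        assert all(b >= a - 1e-12 for a, b in zip(fids, fids[1:]))
        assert fids[-1] == pytest.approx(1.0, abs=1e-12)


class TestApplyMpo:
    def test_identity_mpo(self, rng):
        st_ = random_dense_state(rng, 3)
        psi = mps_from_dense(st_, 0.0)
        out = apply_mpo(identity_mpo(3), psi)
        assert np.abs(mps_to_dense(out).amplitudes - st_.amplitudes).max() < 1e-14

    @pytest.mark.parametrize("p,q", [(0, 2), (2, 0), (1, 1), (3, 1), (0, 3)])
    def test_excitation_matches_dense_fermionic_action(self, rng, p, q):
        L = 4
        st_ = random_dense_state(rng, L)
        psi = mps_from_dense(st_, 0.0)
        lhs = mps_to_dense(apply_mpo(excitation_mpo(p, q, L), psi)).amplitudes
        rhs = dense_excitation(L, p, q) @ st_.amplitudes
        assert np.abs(lhs - rhs).max() < 1e-12

    def test_sign_across_occupied_intervening_orbital(self):
        # E_02 on |0_up, 1_updown, 2_up>: the JW string over the doubly
        # occupied middle orbital contributes (+1)(-1)(-1) per channel pair
        L = 3
        v = np.zeros(64)
        v[DenseState.occupations_to_index([0, 3, 1])] = 1.0
        psi = mps_from_dense(DenseState(v), 0.0)
        lhs = mps_to_dense(apply_mpo(excitation_mpo(0, 2, L), psi)).amplitudes
        rhs = dense_excitation(L, 0, 2) @ v
        assert np.abs(lhs - rhs).max() < 1e-14
        assert np.abs(rhs).max() > 0  # the move is allowed

    def test_output_bond_dims_bounded_by_b_times_m(self, rng):
        L = 4
        psi = mps_from_dense(random_dense_state(rng, L), 0.0)
        op = excitation_mpo(0, 3, L)
        out = apply_mpo(op, psi)
        b = op.max_bond_dim
        for l in range(L + 1):
            assert out.bond_dims[l] <= b * psi.bond_dims[l]

    def test_length_mismatch(self, rng):
        psi = mps_from_dense(random_dense_state(rng, 3), 0.0)
        with pytest.raises(ShapeError):
            apply_mpo(identity_mpo(4), psi)


class TestAddScale:
    def test_add_matches_dense_sum(self, rng):
        a = random_dense_state(rng, 4)
        b = random_dense_state(rng, 4)
        s = add(mps_from_dense(a, 0.0), mps_from_dense(b, 0.0))
        assert np.abs(
            mps_to_dense(s).amplitudes - (a.amplitudes + b.amplitudes)
        ).max() < 1e-12

    def test_add_zero_state(self, rng):
        a = random_dense_state(rng, 3)
        pa = mps_from_dense(a, 0.0)
        zero = scale(pa, 0.0)
        s = mps_to_dense(add(pa, zero))
        assert np.abs(s.amplitudes - a.amplitudes).max() < 1e-12

    def test_bond_dims_additive(self, rng):
        pa = mps_from_dense(random_dense_state(rng, 4), 0.0)
        pb = mps_from_dense(random_dense_state(rng, 4), 0.0)
        s = add(pa, pb)
        for l in range(1, 4):
            assert s.bond_dims[l] == pa.bond_dims[l] + pb.bond_dims[l]

    def test_add_respects_log_scales(self, rng):
        a = random_dense_state(rng, 3)
        pa = mps_from_dense(a, 0.0)
        pb = scale(pa, -3.0)
        s = mps_to_dense(add(pa, pb))
        assert np.abs(s.amplitudes - (-2.0) * a.amplitudes).max() < 1e-12

    @pytest.mark.parametrize("factor", [1.0, 0.5, -2.0])
    def test_scale_matches_dense(self, rng, factor):
        a = random_dense_state(rng, 3)
        out = mps_to_dense(scale(mps_from_dense(a, 0.0), factor))
        assert np.abs(out.amplitudes - factor * a.amplitudes).max() < 1e-12

    def test_half_scale_quarters_norm_squared(self, rng):
        psi = mps_from_dense(random_dense_state(rng, 3), 0.0)
        assert scale(psi, 0.5).norm_squared() == pytest.approx(0.25, abs=1e-12)


class TestExcitationOperatorAlgebra:
    def test_number_operator_eigenvalues(self):
        L = 2
        for k, occ in [(0, 0.0), (1, 1.0), (2, 1.0), (3, 2.0)]:
            v = np.zeros(16)
            v[DenseState.occupations_to_index([k, 0])] = 1.0
            psi = mps_from_dense(DenseState(v), 0.0)
            out = mps_to_dense(apply_mpo(excitation_mpo(0, 0, L), psi))
            assert np.abs(out.amplitudes - occ * v).max() < 1e-14

    def test_two_electron_operator_identity(self):
        # e_{pk,qk} = E_pk E_qk - delta_kq E_pk, checked densely on L=3
        L = 3
        for p, q, k in [(0, 1, 2), (1, 2, 0), (0, 2, 1), (0, 1, 1)]:
            Epk = dense_excitation(L, p, k).toarray()
            Eqk = dense_excitation(L, q, k).toarray()
            lhs = Epk @ Eqk - (1.0 if k == q else 0.0) * Epk
            # the two-electron operator built directly in normal order:
            # sum_st a+_ps a+_qt a_kt a_ks
            from mpssi.oracle import dense_annihilation

            rhs = np.zeros_like(lhs)
            for s in (0, 1):
                for t in (0, 1):
                    rhs += (
                        dense_annihilation(L, p, s).T
                        @ dense_annihilation(L, q, t).T
                        @ dense_annihilation(L, k, t)
                        @ dense_annihilation(L, k, s)
                    ).toarray()
            assert np.abs(lhs - rhs).max() < 1e-12


class TestSpinSquared:
    def test_parallel_spins_triplet(self):
        v = np.zeros(16)
        v[DenseState.occupations_to_index([1, 1])] = 1.0  # |up, up>
        assert spin_squared_expectation(mps_from_dense(DenseState(v), 0.0)) == (
            pytest.approx(2.0, abs=1e-12)
        )

    def test_open_shell_singlet(self):
        v = np.zeros(16)
        v[DenseState.occupations_to_index([1, 2])] = 1 / np.sqrt(2)
        v[DenseState.occupations_to_index([2, 1])] = -1 / np.sqrt(2)
        assert spin_squared_expectation(mps_from_dense(DenseState(v), 0.0)) == (
            pytest.approx(0.0, abs=1e-12)
        )

    @pytest.mark.parametrize("L", [2, 3, 4])
    def test_matches_dense_quadratic_form(self, rng, L):
        st_ = random_dense_state(rng, L)
        val = spin_squared_expectation(mps_from_dense(st_, 0.0))
        ref = st_.amplitudes @ (dense_spin_squared(L) @ st_.amplitudes)
        assert val == pytest.approx(ref, abs=1e-10)

    def test_zero_norm_rejected(self, rng):
        psi = scale(mps_from_dense(random_dense_state(rng, 2), 0.0), 0.0)
        with pytest.raises(MalformedStateError):
            spin_squared_expectation(psi)
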