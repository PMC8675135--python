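"""The sequential MPS counter-rotation, validated against dense oracles."""

import warnings

import numpy as np
import pytest
from scipy.stats import linregress

from mpssi.biortho import biorthonormalize, counter_rotation_data, mo_overlap
from mpssi.core_mps import (
    DenseState,
    apply_mpo,
    inner,
    mps_from_dense,
    mps_to_dense,
)
from mpssi.counterrotate import (
    RotationPlan,
    build_rotation_mpo,
    counter_rotate,
    site_scale,
)
from mpssi.exceptions import ConfigError
from mpssi.oracle import dense_excitation, dense_state_overlap
from mpssi.synthetic import build_scan, random_orbital_pair

from conftest import random_dense_state, random_sector_state


def exact_m(L):
    return 4 ** (L // 2 + 1)


def rotation_setup(L, theta, seed):
    pair = random_orbital_pair(L, 0, theta, seed)
    S = mo_overlap(pair)
    bio = biorthonormalize(S)
    return S, counter_rotation_data(bio.C_XA, 0), counter_rotation_data(bio.C_YB, 0)


class TestSiteScale:
    def test_unit_factor_is_identity(self, rng):
        st = random_dense_state(rng, 3)
        psi = mps_from_dense(st, 0.0)
        out = mps_to_dense(site_scale(psi, 1, 1.0))
        ref = mps_to_dense(psi)
        assert np.array_equal(out.amplitudes, ref.amplitudes)

    def test_doubly_occupied_rule(self):
        v = np.zeros(16)
        v[DenseState.occupations_to_index([3, 0])] = 1.0
        psi = mps_from_dense(DenseState(v), 0.0)
        out = mps_to_dense(site_scale(psi, 0, 0.5))
        assert np.abs(out.amplitudes - 0.25 * v).max() < 1e-15

    def test_matches_dense_diagonal_operator(self, rng):
        L, l, t_ll = 4, 2, 0.7
        st = random_dense_state(rng, L)
        psi = mps_from_dense(st, 0.0)
        out = mps_to_dense(site_scale(psi, l, t_ll)).amplitudes
        diag = np.ones(4**L)
        ks = (np.arange(4**L) // 4 ** (L - 1 - l)) % 4
        diag[ks == 1] = t_ll
        diag[ks == 2] = t_ll
        diag[ks == 3] = t_ll**2
        assert np.abs(out - diag * st.amplitudes).max() < 1e-12

    def test_out_of_range_site(self, rng):
        psi = mps_from_dense(random_dense_state(rng, 2), 0.0)
        with pytest.raises(IndexError):
            site_scale(psi, 5, 1.0)


class TestRotationMpo:
    def test_zero_offdiagonals_give_identity_operator(self, rng):
        t = np.diag([0.9, 1.1, 0.8])
        op = build_rotation_mpo(t, 1, "linear")
        st = random_dense_state(rng, 3)
        out = mps_to_dense(apply_mpo(op, mps_from_dense(st, 0.0)))
        assert np.abs(out.amplitudes - st.amplitudes).max() < 1e-14

    def test_two_orbital_linear_operator(self, rng):
        # t_21/t_11 = c  ->  dense operator I + c E_21
        c = 0.37
        t = np.eye(2)
        t[1, 0] = c
        op = build_rotation_mpo(t, 0, "linear")
        st = random_dense_state(rng, 2)
        out = mps_to_dense(apply_mpo(op, mps_from_dense(st, 0.0))).amplitudes
        ref = st.amplitudes + c * (dense_excitation(2, 1, 0) @ st.amplitudes)
        assert np.abs(out - ref).max() < 1e-14

    @pytest.mark.parametrize("L,l", [(3, 0), (4, 2), (5, 4)])
    def test_documented_bond_dimension_bound(self, rng, L, l):
        t = np.eye(L) + 0.1 * rng.standard_normal((L, L))
        op = build_rotation_mpo(t, l, "linear")
        assert op.max_bond_dim <= 4

    def test_generator_mode_matches_dense(self, rng):
        L, l = 3, 1
        t = np.eye(L) + 0.2 * rng.standard_normal((L, L))
        op = build_rotation_mpo(t, l, "quadratic-term")
        st = random_dense_state(rng, L)
        out = mps_to_dense(apply_mpo(op, mps_from_dense(st, 0.0))).amplitudes
        that = np.zeros((4**L, 4**L))
        for p in range(L):
            if p != l:
                that += (t[p, l] / t[l, l]) * dense_excitation(L, p, l).toarray()
        assert np.abs(out - that @ st.amplitudes).max() < 1e-12

    def test_zero_diagonal_rejected(self):
        t = np.eye(2)
        t[0, 0] = 0.0
        with pytest.raises(ConfigError):
            build_rotation_mpo(t, 0, "linear")


class TestCounterRotate:
    @pytest.mark.parametrize("mode", ["full", "approximate"])
    def test_identity_rotation_is_exact(self, rng, mode):
        L = 4
        st = random_dense_state(rng, L)
        psi = mps_from_dense(st, 0.0)
        rot = counter_rotation_data(np.eye(L), 0)
        res = counter_rotate(psi, rot, RotationPlan(mode=mode, m_compress=64))
        out = mps_to_dense(res.psi_out)
        assert np.abs(out.amplitudes - st.amplitudes).max() < 1e-12
        assert res.deviation_norm_used == 0.0

    @pytest.mark.parametrize("L", [2, 3, 4, 5])
    def test_full_mode_reproduces_lowdin_oracle(self, rng, L):
        """Primary correctness surface: full mode at exact m equals the
        nonorthogonal-determinant overlap for sector-restricted states."""
        for trial in range(4):
            theta = rng.uniform(0.05, 0.4)
            n_elec = int(rng.integers(1, 2 * L))
            S, rotA, rotB = rotation_setup(L, theta, int(rng.integers(2**31)))
            a = random_sector_state(rng, L, n_elec)
            b = random_sector_state(rng, L, n_elec)
            exact = dense_state_overlap(a, b, S)
            plan = RotationPlan(mode="full", m_compress=exact_m(L))
            A = counter_rotate(mps_from_dense(a, 0.0), rotA, plan).psi_out
            B = counter_rotate(mps_from_dense(b, 0.0), rotB, plan).psi_out
            assert abs(np.real(inner(A, B)) - exact) < 1e-8

    def test_frozen_core_alpha_against_dense_oracle(self, rng):
        """Inactive orbitals enter only through alpha; validated against the
        dense overlap including the explicitly doubly occupied core."""
        # alpha departs from 1 only when the retained orbital spaces are
        # truncated (virtuals dropped), making the inactive block of S^XY
        # non-orthogonal: rotate the inactive orbitals into a discarded
        # virtual, keeping the active block decoupled
        from scipy.linalg import expm

        n_in, n_act = 2, 2
        L_tot = n_in + n_act
        n_ao = L_tot + 1
        K = np.zeros((n_ao, n_ao))
        mix = [0, 1, 4]  # inactive orbitals + the dropped virtual
        A = np.random.default_rng(17).standard_normal((3, 3))
        K[np.ix_(mix, mix)] = A - A.T
        K[2, 3] = 0.4
        K[3, 2] = -0.4  # active-active rotation
        from mpssi.biortho import OrbitalBasisPair

        pair = OrbitalBasisPair(
            C_X=np.eye(n_ao)[:, :L_tot],
            C_Y=expm(0.3 * K)[:, :L_tot],
            S_AO=np.eye(n_ao),
            n_inactive=n_in,
            n_active=n_act,
        )
        S = mo_overlap(pair)
        bio = biorthonormalize(S)
        rotA = counter_rotation_data(bio.C_XA, n_in)
        rotB = counter_rotation_data(bio.C_YB, n_in)
        assert rotA.alpha != pytest.approx(1.0)
        # active-space states, embedded with a doubly occupied core orbital
        a_act = random_dense_state(rng, n_act)
        b_act = random_dense_state(rng, n_act)

        def embed(act):
            full = np.zeros(4**L_tot)
            for i, amp in enumerate(act.amplitudes):
                ks = (3,) * n_in + DenseState.index_to_occupations(i, n_act)
                full[DenseState.occupations_to_index(ks)] = amp
            return DenseState(full, L_tot)

        exact = dense_state_overlap(embed(a_act), embed(b_act), S)
        plan = RotationPlan(mode="full", m_compress=16)
        A = counter_rotate(mps_from_dense(a_act, 0.0), rotA, plan).psi_out
        B = counter_rotate(mps_from_dense(b_act, 0.0), rotB, plan).psi_out
        assert abs(np.real(inner(A, B)) - exact) < 1e-10

    def test_approximation_error_is_second_order(self):
        fam = build_scan(4, 4, [0.02, 0.04, 0.08, 0.16], seed=7)
        fit = linregress(
            np.log([p.theta for p in fam.points]), np.log(fam.approx_errors)
        )
        assert fit.slope >= 1.7

    def test_fidelity_non_decreasing_in_m_and_spin_monitor(self, rng):
        # the monitor needs a spin eigenstate: the spin-summed rotation
        # commutes with S^2, so <S^2> is preserved exactly at exact m and
        # moves only under truncation
        from mpssi.synthetic import toy_hamiltonian_states

        L = 4
        _, rotA, _ = rotation_setup(L, 0.35, 23)
        st = toy_hamiltonian_states(L, 4, n_states=2)[0][1]
        psi = mps_from_dense(st, 0.0)
        ref = counter_rotate(
            psi, rotA, RotationPlan(mode="full", m_compress=exact_m(L))
        )
        assert abs(ref.spin_sq_after - ref.spin_sq_before) < 1e-8
        fids = []
        for m in (1, 2, 4, 8, exact_m(L)):
            res = counter_rotate(psi, rotA, RotationPlan(mode="full", m_compress=m))
            num = abs(inner(ref.psi_out, res.psi_out)) ** 2
            den = ref.psi_out.norm_squared() * res.psi_out.norm_squared()
            fids.append(num / den)
        assert all(b >= a - 1e-10 for a, b in zip(fids, fids[1:]))
        assert fids[-1] == pytest.approx(1.0, abs=1e-10)

    def test_truncation_reports_discarded_weight(self, rng):
        L = 4
        _, rotA, _ = rotation_setup(L, 0.35, 29)
        psi = mps_from_dense(random_dense_state(rng, L), 0.0)
        res = counter_rotate(psi, rotA, RotationPlan(mode="full", m_compress=2))
        assert res.total_discarded_weight > 0
        assert len(res.psi_out.site_tensors) == L

    def test_cutoff_warning_in_approximate_mode(self, rng):
        L = 3
        _, rotA, _ = rotation_setup(L, 1.4, 31)
        assert rotA.deviation_norm >= 1.0
        psi = mps_from_dense(random_dense_state(rng, L), 0.0)
        with pytest.warns(UserWarning, match="cutoff"):
            counter_rotate(
                psi, rotA, RotationPlan(mode="approximate", m_compress=exact_m(L))
            )

    def test_per_site_report_filled(self, rng):
        L = 3
        _, rotA, _ = rotation_setup(L, 0.2, 37)
        plan = RotationPlan(mode="full", m_compress=exact_m(L))
        counter_rotate(mps_from_dense(random_dense_state(rng, L), 0.0), rotA, plan)
        assert len(plan.per_site_report) == L

    def test_invalid_plan_rejected(self):
        with pytest.raises(ConfigError):
            RotationPlan(mode="full", m_compress=0)
        with pytest.raises(ConfigError):
            RotationPlan(mode="sideways")
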