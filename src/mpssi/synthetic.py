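"""Synthetic generators for every input the method consumes.

Real applications feed this package from multiconfigurational (DMRG-SCF)
calculations; here, pairs of nearly parallel orbital sets are produced by
exponentiating seeded antisymmetric generators, many-electron states come
from exact diagonalization of a short Hubbard chain (the smallest standard
model with nontrivial singlet/triplet manifolds), and spin-orbit integrals
are random Hermitian purely imaginary matrices.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import expm

from .biortho import (
    OrbitalBasisPair,
    biorthonormalize,
    counter_rotation_data,
    mo_overlap,
)
from .core_mps import DenseState, inner, mps_from_dense
from .counterrotate import RotationPlan, counter_rotate
from .exceptions import ConfigError, SpinPurityError
from .oracle import (
    dense_annihilation,
    dense_number,
    dense_spin_squared,
    dense_state_overlap,
    dense_sz,
)
from .state_interaction import SOCIntegrals

__all__ = [
    "ScanFamily",
    "ScanPoint",
    "random_orbital_pair",
    "toy_hamiltonian_states",
    "toy_multiplet_states",
    "make_soc_integrals",
    "build_scan",
    "hubbard_hamiltonian",
]

DEFAULT_T_HOP = 1.0
DEFAULT_U = 4.0


def random_orbital_pair(
    L_tot: int, n_inactive: int, theta: float, seed: int
) -> OrbitalBasisPair:
    """Orbital-set pair differing by a rotation of magnitude ``theta``.

    ``C_X = I`` and ``C_Y = expm(theta * K)`` for a seeded random
    antisymmetric ``K`` normalized to unit Frobenius norm, so ``theta``
    directly controls the rotation magnitude.  ``K`` is block diagonal
    over the inactive/active split: the method treats inactive orbitals by
    a scalar only, so the generator respects that assumption.
    """
    if theta < 0:
        raise ConfigError("theta must be non-negative")
    rng = np.random.default_rng(seed)
    K = np.zeros((L_tot, L_tot))
    for blk in (slice(0, n_inactive), slice(n_inactive, L_tot)):
        n = blk.stop - blk.start
        if n > 1:
            A = rng.standard_normal((n, n))
            K[blk, blk] = A - A.T
    nrm = np.linalg.norm(K)
    if nrm > 0:
        K /= nrm
    C_Y = expm(theta * K)
    return OrbitalBasisPair(
        C_X=np.eye(L_tot),
        C_Y=C_Y,
        S_AO=np.eye(L_tot),
        n_inactive=n_inactive,
        n_active=L_tot - n_inactive,
    )


def hubbard_hamiltonian(
    L: int, t_hop: float = DEFAULT_T_HOP, U: float = DEFAULT_U
) -> sp.csr_matrix:
    """Nearest-neighbor hopping + on-site repulsion chain over the full
    ``4**L`` occupation basis."""
    H = sp.csr_matrix((4**L, 4**L))
    for l in range(L - 1):
        for s in (0, 1):
            hop = dense_annihilation(L, l + 1, s).T @ dense_annihilation(L, l, s)
            H = H - t_hop * (hop + hop.T)
    for l in range(L):
        n_up = dense_annihilation(L, l, 0).T @ dense_annihilation(L, l, 0)
        n_dn = dense_annihilation(L, l, 1).T @ dense_annihilation(L, l, 1)
        H = H + U * (n_up @ n_dn)
    return H.tocsr()


def _sector_indices(L: int, n_elec: int, sz: float) -> np.ndarray:
    n = dense_number(L).diagonal()
    z = dense_sz(L).diagonal()
    return np.nonzero((n == n_elec) & (np.abs(z - sz) < 1e-12))[0]


def _spin_purify(vals, vecs, S2sub, degeneracy_tol=1e-8):
    """Rotate degenerate eigenvector clusters into S^2 eigenvectors."""
    out = np.array(vecs, dtype=float, copy=True)
    spins = np.empty(vals.size)
    i = 0
    while i < vals.size:
        j = i + 1
        while j < vals.size and vals[j] - vals[i] < degeneracy_tol * max(
            1.0, abs(vals[i])
        ):
            j += 1
        block = out[:, i:j]
        s2 = block.T @ S2sub @ block
        w, v = np.linalg.eigh(0.5 * (s2 + s2.T))
        out[:, i:j] = block @ v
        spins[i:j] = w
        i = j
    return out, spins


def _fix_phase(vec: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    nz = np.nonzero(np.abs(vec) > tol)[0]
    if nz.size and vec[nz[0]].real < 0:
        return -vec
    return vec


def toy_hamiltonian_states(
    L: int,
    N_elec: int,
    t_hop: float = DEFAULT_T_HOP,
    U: float = DEFAULT_U,
    n_states: int = 3,
    seed: int = 0,
    sz: float | None = None,
):
    """Lowest spin-pure eigenstates of the Hubbard chain in one
    ``(N, S_z)`` sector.

    Degenerate multiplets are disentangled by subspace diagonalization of
    ``S^2``; phases are fixed by making the first sizable amplitude real
    positive.  Returns ``(states, energies, spins)`` with ``spins`` a list
    of ``(S, M)`` labels and eigen-residuals below 1e-10.  ``seed`` is
    accepted for interface uniformity; the construction is deterministic.
    """
    del seed
    if not 0 <= N_elec <= 2 * L:
        raise ConfigError(f"electron count {N_elec} out of range for L={L}")
    if sz is None:
        sz = 0.0 if N_elec % 2 == 0 else 0.5
    idx = _sector_indices(L, N_elec, sz)
    if idx.size < n_states:
        raise ConfigError(
            f"sector (N={N_elec}, Sz={sz}) has dimension {idx.size} < "
            f"{n_states} requested states"
        )
    H = hubbard_hamiltonian(L, t_hop, U)
    Hsub = H[np.ix_(idx, idx)].toarray()
    S2sub = dense_spin_squared(L)[np.ix_(idx, idx)].toarray()
    vals, vecs = np.linalg.eigh(0.5 * (Hsub + Hsub.T))
    vecs, s2vals = _spin_purify(vals, vecs, S2sub)
    states, energies, spins = [], [], []
    for k in range(n_states):
        v = _fix_phase(vecs[:, k])
        resid = np.linalg.norm(Hsub @ v - vals[k] * v)
        if resid > 1e-10:
            raise RuntimeError(f"eigen-residual {resid:.2e} too large")
        S = 0.5 * (-1.0 + np.sqrt(1.0 + 4.0 * max(s2vals[k], 0.0)))
        S = round(2 * S) / 2
        if abs(v @ (S2sub @ v) - S * (S + 1)) > 1e-8:
            raise SpinPurityError(f"state {k} is not spin-pure after projection")
        full = np.zeros(4**L)
        full[idx] = v
        states.append(DenseState(full, L))
        energies.append(float(vals[k]))
        spins.append((S, sz))
    return states, energies, spins


def toy_multiplet_states(
    L: int,
    N_elec: int,
    n_singlets: int,
    n_triplets: int,
    t_hop: float = DEFAULT_T_HOP,
    U: float = DEFAULT_U,
):
    """Lowest singlets (from the Sz=0 sector) and lowest triplets as their
    ``M = S = 1`` members (from the Sz=1 sector), for spin-orbit
    state-interaction demos.  Returns ``(states, energies, spins)``."""
    states, energies, spins = [], [], []
    if n_singlets:
        cand = _collect_spin(L, N_elec, sz=0.0, S_want=0.0, n=n_singlets,
                             t_hop=t_hop, U=U)
        for v, e in cand:
            states.append(v)
            energies.append(e)
            spins.append((0.0, 0.0))
    if n_triplets:
        cand = _collect_spin(L, N_elec, sz=1.0, S_want=1.0, n=n_triplets,
                             t_hop=t_hop, U=U)
        for v, e in cand:
            states.append(v)
            energies.append(e)
            spins.append((1.0, 1.0))
    return states, energies, spins


def _collect_spin(L, N_elec, sz, S_want, n, t_hop, U):
    idx = _sector_indices(L, N_elec, sz)
    H = hubbard_hamiltonian(L, t_hop, U)
    Hsub = H[np.ix_(idx, idx)].toarray()
    S2sub = dense_spin_squared(L)[np.ix_(idx, idx)].toarray()
    vals, vecs = np.linalg.eigh(0.5 * (Hsub + Hsub.T))
    vecs, s2vals = _spin_purify(vals, vecs, S2sub)
    out = []
    for k in range(vals.size):
        S = round(2 * 0.5 * (-1 + np.sqrt(1 + 4 * max(s2vals[k], 0)))) / 2
        if S == S_want:
            full = np.zeros(4**L)
            full[idx] = _fix_phase(vecs[:, k])
            out.append((DenseState(full, L), float(vals[k])))
            if len(out) == n:
                return out
    raise ConfigError(
        f"sector (N={N_elec}, Sz={sz}) holds only {len(out)} states with "
        f"S={S_want}, {n} requested"
    )


def make_soc_integrals(L: int, scale: float, seed: int, unit: str = "hartree"):
    """Random Hermitian, purely imaginary one-electron SOC integrals:
    ``h_k = i * scale * (A_k - A_k.T)`` for seeded standard-normal A_k."""
    if scale < 0:
        raise ConfigError("scale must be non-negative")
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(3):
        A = rng.standard_normal((L, L))
        mats.append(1j * scale * (A - A.T))
    return SOCIntegrals(h_x=mats[0], h_y=mats[1], h_z=mats[2], unit=unit)


@dataclass
class ScanPoint:
    theta: float
    deviation_norm: float
    deviation_norm_bra: float
    deviation_norm_ket: float
    exceeds_cutoff: bool
    error_full: float
    error_approx: float
    overlap_oracle: np.ndarray
    overlap_full: np.ndarray
    overlap_approx: np.ndarray


@dataclass
class ScanFamily:
    """Synthetic analogue of a rigid geometry scan: the orbital rotation
    grows along ``thetas`` while the reference states stay fixed, tracing
    how the linearized counter-rotation degrades with the deviation
    norm."""

    thetas: list[float]
    K_seed: int
    cutoff: float
    points: list[ScanPoint] = field(default_factory=list)

    @property
    def deviation_norms(self) -> np.ndarray:
        return np.array([p.deviation_norm for p in self.points])

    @property
    def approx_errors(self) -> np.ndarray:
        return np.array([p.error_approx for p in self.points])


def build_scan(
    L: int,
    N_elec: int,
    thetas,
    seed: int,
    n_states: int = 3,
    t_hop: float = DEFAULT_T_HOP,
    U: float = DEFAULT_U,
    cutoff: float = 1.0,
) -> ScanFamily:
    """Overlap-accuracy scan over rotation magnitudes.

    At every ``theta`` the same toy-Hamiltonian eigenstates are read as
    wave functions of basis X (reference) and of the rotated basis Y; the
    exact overlaps come from the dense Löwdin-rule oracle, the MPS-side
    overlaps from full and approximate counter-rotation at exact bond
    dimension.  ``error_full`` is the mean absolute deviation of the full
    scheme from the oracle, ``error_approx`` that of the approximate
    scheme from the full one.
    """
    thetas = list(thetas)
    if any(b <= a for a, b in zip(thetas, thetas[1:])):
        raise ConfigError("thetas must be strictly ascending")
    dense_states, _, _ = toy_hamiltonian_states(
        L, N_elec, t_hop=t_hop, U=U, n_states=n_states
    )
    kets = [mps_from_dense(s, 0.0) for s in dense_states]
    m_exact = 4 ** (L // 2 + 1)
    fam = ScanFamily(thetas=thetas, K_seed=seed, cutoff=cutoff)
    for theta in thetas:
        pair = random_orbital_pair(L, 0, theta, seed)
        S_XY = mo_overlap(pair)
        bio = biorthonormalize(S_XY)
        rotA = counter_rotation_data(bio.C_XA, 0)
        rotB = counter_rotation_data(bio.C_YB, 0)
        n = len(kets)
        O_oracle = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                O_oracle[i, j] = np.real(
                    dense_state_overlap(dense_states[i], dense_states[j], S_XY)
                )
        transformed = {}
        for mode in ("full", "approximate"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                A = [
                    counter_rotate(k, rotA, RotationPlan(mode=mode, m_compress=m_exact)).psi_out
                    for k in kets
                ]
                B = [
                    counter_rotate(k, rotB, RotationPlan(mode=mode, m_compress=m_exact)).psi_out
                    for k in kets
                ]
            O = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    O[i, j] = np.real(inner(A[i], B[j]))
            transformed[mode] = O
        dev_bra = rotA.deviation_norm
        dev_ket = rotB.deviation_norm
        dev = max(dev_bra, dev_ket)
        fam.points.append(
            ScanPoint(
                theta=theta,
                deviation_norm=dev,
                deviation_norm_bra=dev_bra,
                deviation_norm_ket=dev_ket,
                exceeds_cutoff=dev >= cutoff,
                error_full=float(np.mean(np.abs(transformed["full"] - O_oracle))),
                error_approx=float(
                    np.mean(np.abs(transformed["approximate"] - transformed["full"]))
                ),
                overlap_oracle=O_oracle,
                overlap_full=transformed["full"],
                overlap_approx=transformed["approximate"],
            )
        )
    return fam
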