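"""Pairwise state-interaction quantities: overlaps, transition densities,
spin-orbit coupling matrices and spin-orbit corrected energies.

The spin-free Hamiltonian is taken diagonal in the supplied per-state
energies: off-diagonal spin-free elements between states of different
orbital bases would require two-electron transition densities and are set
to zero, following common state-interaction practice for separately
optimized multiplets.  On a nonorthogonal state basis the diagonal-energy
operator is symmetrized as ``(diag(E) @ S + S @ diag(E)) / 2`` before the
generalized eigensolve; alternative conventions differ at second order in
``S - I``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core_mps import MPS, apply_mpo, inner, scale, spin_squared_expectation
from .exceptions import ConfigError, ShapeError, SpinPurityError
from .operators import excitation_mpo, total_spin_lowering_mpo

__all__ = [
    "StateSet",
    "SOCIntegrals",
    "SIResult",
    "pairwise_overlaps",
    "transition_1rdm",
    "soc_matrix",
    "si_eigensolve",
    "complete_multiplets",
    "HARTREE_PER_CM1",
]

#: 1 cm^-1 in hartree.
HARTREE_PER_CM1 = 1.0 / 219474.6313632


@dataclass
class StateSet:
    """States sharing one representation, with spin labels ``(S, M)`` and
    externally supplied spin-free energies in hartree."""

    states: list[MPS]
    spins: list[tuple[float, float]]
    energies: list[float]

    def __post_init__(self) -> None:
        if not (len(self.states) == len(self.spins) == len(self.energies)):
            raise ShapeError("states, spins and energies must align")

    def validate_spins(self, tol: float = 1e-6) -> None:
        for i, (psi, (S, _M)) in enumerate(zip(self.states, self.spins)):
            s2 = spin_squared_expectation(psi)
            if abs(s2 - S * (S + 1)) > tol:
                raise SpinPurityError(
                    f"state {i}: <S^2> = {s2:.6f} inconsistent with S = {S}"
                )

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class SOCIntegrals:
    """One-electron spin-orbit integrals over the active orbitals.

    Hermitian with purely imaginary entries (hence zero diagonal), as
    produced by mean-field spin-orbit operators over real orbitals.
    """

    h_x: np.ndarray
    h_y: np.ndarray
    h_z: np.ndarray
    unit: str = "hartree"

    def __post_init__(self) -> None:
        if self.unit not in ("hartree", "cm-1"):
            raise ConfigError(f"unknown SOC unit {self.unit!r}")
        for name in ("h_x", "h_y", "h_z"):
            h = np.asarray(getattr(self, name), dtype=complex)
            setattr(self, name, h)
            if h.shape != self.h_x.shape or h.ndim != 2 or h.shape[0] != h.shape[1]:
                raise ShapeError(f"{name} must be square and consistent")
            if not np.allclose(h, h.conj().T, atol=1e-12):
                raise ShapeError(f"{name} is not Hermitian")
            if not np.allclose(h.real, 0.0, atol=1e-12):
                raise ShapeError(f"{name} must be purely imaginary")

    @property
    def L(self) -> int:
        return self.h_x.shape[0]

    def in_hartree(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = HARTREE_PER_CM1 if self.unit == "cm-1" else 1.0
        return self.h_x * f, self.h_y * f, self.h_z * f


@dataclass
class SIResult:
    """Spin-orbit state-interaction eigenproblem output (energies in
    hartree, ascending)."""

    overlap_matrix: np.ndarray
    soc_matrix: np.ndarray
    corrected_energies: np.ndarray
    eigvectors: np.ndarray

    @property
    def corrected_energies_cm1(self) -> np.ndarray:
        return self.corrected_energies / HARTREE_PER_CM1


def pairwise_overlaps(setA: StateSet, setB: StateSet) -> np.ndarray:
    """Overlap matrix ``O_ij = <A_i|B_j>`` by plain coefficient
    contraction; equals the physical nonorthogonal-basis overlaps once
    both sets are counter-rotated into conjugate biorthonormal bases."""
    out = np.empty((len(setA), len(setB)), dtype=complex)
    for i, a in enumerate(setA.states):
        for j, b in enumerate(setB.states):
            out[i, j] = inner(a, b)
    if np.allclose(out.imag, 0.0):
        return out.real
    return out


def transition_1rdm(A: MPS, B: MPS, spin_resolved: bool = False):
    """Transition one-particle density between two MPSs in a shared
    (biorthonormal) representation.

    ``D[p, q] = <A|E_pq|B>`` or, spin-resolved,
    ``D[s, t, p, q] = <A|a+_{p,s} a_{q,t}|B>`` with s, t in (up, dn).
    """
    if A.L != B.L:
        raise ShapeError("site counts differ")
    L = A.L
    names = ("up", "down")
    if spin_resolved:
        D = np.zeros((2, 2, L, L), dtype=complex)
        for s in (0, 1):
            for t in (0, 1):
                for p in range(L):
                    for q in range(L):
                        op = excitation_mpo(p, q, L, spins=(names[s], names[t]))
                        D[s, t, p, q] = inner(A, apply_mpo(op, B))
        return D
    D = np.zeros((L, L), dtype=complex)
    for p in range(L):
        for q in range(L):
            D[p, q] = inner(A, apply_mpo(excitation_mpo(p, q, L), B))
    return D


def complete_multiplets(stateset: StateSet, tol: float = 1e-6) -> StateSet:
    """Expand each ``M = S`` multiplet member into all ``2S + 1``
    components by repeated total-spin lowering.

    ``S- |S, M> = sqrt(S(S+1) - M(M-1)) |S, M-1>`` fixes the
    Condon-Shortley phases, so each lowered state is divided by that
    factor rather than renormalized blindly.
    """
    stateset.validate_spins(tol)
    states: list[MPS] = []
    spins: list[tuple[float, float]] = []
    energies: list[float] = []
    for psi, (S, M), E in zip(stateset.states, stateset.spins, stateset.energies):
        if abs(M - S) > tol:
            raise SpinPurityError(
                f"multiplet expansion expects the M = S member, got M = {M}"
            )
        lower = total_spin_lowering_mpo(psi.L)
        cur = psi
        states.append(cur)
        spins.append((S, S))
        energies.append(E)
        m = S
        while m > -S + tol:
            factor = np.sqrt(S * (S + 1) - m * (m - 1))
            cur = scale(apply_mpo(lower, cur), 1.0 / factor)
            m -= 1
            states.append(cur)
            spins.append((S, m))
            energies.append(E)
    return StateSet(states, spins, energies)


def soc_matrix(
    setS: StateSet,
    setT: StateSet,
    soc: SOCIntegrals,
    W_bra: np.ndarray | None = None,
    W_ket: np.ndarray | None = None,
    validate: bool = True,
) -> np.ndarray:
    """Spin-orbit coupling matrix ``<i, S_i M_i| H_SO |j, S_j M_j>``.

    Assembled by contracting spin-resolved transition densities with the
    Pauli form of the one-electron SOC operator,
    ``H_SO = sum_pq sum_k h^k_pq (1/2) sum_st sigma^k_st a+_ps a_qt``.
    Both sets must enumerate every M component explicitly (use
    :func:`complete_multiplets`); elements are returned in hartree.

    ``W_bra`` / ``W_ket`` optionally give the active-orbital coefficients
    of the bra and ket representations in the basis the integrals are
    expressed in; the integral block used is then ``W_bra.T @ h @ W_ket``
    (needed for states counter-rotated into a biorthonormal pair; spin
    labels cannot be validated on such states by plain contraction, so
    pass ``validate=False`` and validate upstream).
    """
    if validate:
        for ss in (setS, setT):
            ss.validate_spins()
            _check_m_components(ss)
    hx, hy, hz = soc.in_hartree()
    if W_bra is not None or W_ket is not None:
        Wb = np.eye(soc.L) if W_bra is None else np.asarray(W_bra)
        Wk = np.eye(soc.L) if W_ket is None else np.asarray(W_ket)
        hx, hy, hz = (Wb.T @ h @ Wk for h in (hx, hy, hz))
    out = np.zeros((len(setS), len(setT)), dtype=complex)
    for i, a in enumerate(setS.states):
        for j, b in enumerate(setT.states):
            D = transition_1rdm(a, b, spin_resolved=True)
            out[i, j] = 0.5 * (
                np.sum(hx * (D[0, 1] + D[1, 0]))
                + np.sum(hy * (-1j * D[0, 1] + 1j * D[1, 0]))
                + np.sum(hz * (D[0, 0] - D[1, 1]))
            )
    return out


def _check_m_components(ss: StateSet) -> None:
    """Multiplets are identified by (S, energy); each must carry every M."""
    groups: dict[tuple[float, float], set[float]] = {}
    for (S, M), E in zip(ss.spins, ss.energies):
        groups.setdefault((S, round(E, 10)), set()).add(round(M, 6))
    for (S, E), ms in groups.items():
        expect = {round(S - k, 6) for k in range(int(round(2 * S)) + 1)}
        missing = sorted(expect - ms)
        if missing:
            raise SpinPurityError(
                f"multiplet S={S} at E={E}: missing M components {missing}"
            )


def si_eigensolve(
    energies, overlap: np.ndarray, soc: np.ndarray
) -> SIResult:
    """Solve the generalized state-interaction eigenproblem.

    ``H = (diag(E) @ S + S @ diag(E)) / 2 + V_SO`` over the metric ``S``;
    returns real eigenvalues ascending with their eigenvectors.
    """
    E = np.asarray(energies, dtype=float)
    S = np.asarray(overlap)
    V = np.asarray(soc)
    n = E.size
    if S.shape != (n, n) or V.shape != (n, n):
        raise ShapeError("dimension mismatch between energies and matrices")
    if not np.allclose(S, S.conj().T, atol=1e-8):
        raise ShapeError("overlap matrix is not Hermitian")
    if not np.allclose(V, V.conj().T, atol=1e-8):
        raise ShapeError("SOC matrix is not Hermitian")
    try:
        np.linalg.cholesky(S if np.iscomplexobj(S) else S.astype(float))
    except np.linalg.LinAlgError as exc:
        raise ShapeError("overlap matrix is not positive definite") from exc
    D = np.diag(E)
    H = 0.5 * (D @ S + S @ D) + V
    H = 0.5 * (H + H.conj().T)
    vals, vecs = scipy.linalg.eigh(H, S)
    return SIResult(
        overlap_matrix=S,
        soc_matrix=V,
        corrected_energies=vals,
        eigvectors=vecs,
    )
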