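"""Brute-force dense-CI reference implementations.

Everything here works on full ``4**L`` amplitude vectors and scales
exponentially on purpose: these routines are the ground truth the MPS-side
algorithms are validated against, so they are kept as simple and as close
to the defining formulas as possible (generalized Löwdin determinant rule
for nonorthogonal determinant overlaps, explicit operator matrices for
densities and spin-orbit elements).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .core_mps import DenseState
from .exceptions import ShapeError, SpinPurityError

__all__ = [
    "Determinant",
    "lowdin_overlap",
    "dense_state_overlap",
    "dense_tdm",
    "dense_soc_element",
    "dense_annihilation",
    "dense_excitation",
    "dense_spin_squared",
    "dense_sz",
    "dense_number",
    "occupation_phase",
    "blocked_amplitudes",
]


# ---------------------------------------------------------------------------
# dense second quantization over the occupation-string basis
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _occ_table(L: int) -> np.ndarray:
    """(4**L, 2L) array of spin-orbital occupations, JW order
    (0up, 0dn, 1up, 1dn, ...)."""
    idx = np.arange(4**L)
    cols = []
    for l in range(L):
        k = (idx // 4 ** (L - 1 - l)) % 4
        cols.append(k & 1)        # n_up
        cols.append((k >> 1) & 1)  # n_dn
    return np.stack(cols, axis=1).astype(np.int8)


@lru_cache(maxsize=None)
def dense_annihilation(L: int, l: int, spin: int) -> sp.csr_matrix:
    """Sparse matrix of ``a_{l,spin}`` (spin: 0=up, 1=dn) over ``4**L``
    occupation strings with Jordan-Wigner signs."""
    occ = _occ_table(L)
    j = 2 * l + spin
    src = np.nonzero(occ[:, j] == 1)[0]
    signs = (-1.0) ** occ[src, :j].sum(axis=1)
    # clearing spin orbital j lowers the base-4 digit of site l
    step = (1 if spin == 0 else 2) * 4 ** (L - 1 - l)
    dst = src - step
    return sp.csr_matrix(
        (signs, (dst, src)), shape=(4**L, 4**L)
    )


def dense_excitation(L: int, p: int, q: int, spins: tuple[int, int] | None = None):
    """Dense-side ``E_pq`` (spin-summed) or ``a+_{p,s} a_{q,t}``."""
    if spins is None:
        out = None
        for s in (0, 1):
            term = dense_annihilation(L, p, s).T @ dense_annihilation(L, q, s)
            out = term if out is None else out + term
        return out
    s, t = spins
    return dense_annihilation(L, p, s).T @ dense_annihilation(L, q, t)


@lru_cache(maxsize=None)
def dense_sz(L: int) -> sp.csr_matrix:
    occ = _occ_table(L)
    sz = 0.5 * (occ[:, 0::2].sum(axis=1) - occ[:, 1::2].sum(axis=1))
    return sp.diags(sz).tocsr()


@lru_cache(maxsize=None)
def dense_number(L: int) -> sp.csr_matrix:
    occ = _occ_table(L)
    return sp.diags(occ.sum(axis=1).astype(float)).tocsr()


@lru_cache(maxsize=None)
def dense_spin_squared(L: int) -> sp.csr_matrix:
    """``S^2 = S- S+ + Sz (Sz + 1)`` built from ladder matrices."""
    sp_tot = None
    for l in range(L):
        term = dense_annihilation(L, l, 0).T @ dense_annihilation(L, l, 1)
        sp_tot = term if sp_tot is None else sp_tot + term
    sm_tot = sp_tot.T
    sz = dense_sz(L)
    return (sm_tot @ sp_tot + sz @ sz + sz).tocsr()


# ---------------------------------------------------------------------------
# nonorthogonal determinant overlaps (Löwdin rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Determinant:
    """Slater determinant given by sorted occupied spatial orbitals per
    spin channel; the operator string is all up creations (ascending)
    followed by all down creations (ascending)."""

    alpha_occ: tuple[int, ...]
    beta_occ: tuple[int, ...]

    def __post_init__(self) -> None:
        for occ in (self.alpha_occ, self.beta_occ):
            if list(occ) != sorted(set(occ)):
                raise ValueError(f"occupations must be sorted and unique: {occ}")


def lowdin_overlap(detX: Determinant, detY: Determinant, S_XY: np.ndarray) -> float:
    """Overlap of two determinants over nonorthogonal orbital sets.

    Equals the product over spin channels of ``det(S_XY[occ_bra, occ_ket])``
    (zero if electron counts differ per channel) -- the generalized overlap
    rule for determinants of nonorthogonal orbitals.
    """
    out = 1.0
    for bra, ket in ((detX.alpha_occ, detY.alpha_occ), (detX.beta_occ, detY.beta_occ)):
        if len(bra) != len(ket):
            return 0.0
        if len(bra) == 0:
            continue
        sub = np.asarray(S_XY)[np.ix_(bra, ket)]
        out *= float(np.linalg.det(sub))
    return out


def occupation_phase(alpha_occ, beta_occ) -> int:
    """Sign relating the interleaved occupation-string creation order to
    the (up block, down block) determinant order.

    Counts the transpositions needed to move every down creation past the
    up creations that sit on later sites.
    """
    alpha = np.asarray(alpha_occ, dtype=int)
    inversions = sum(int(np.sum(alpha > b)) for b in beta_occ)
    return -1 if inversions % 2 else 1


def blocked_amplitudes(state: DenseState):
    """Regroup a dense amplitude vector into sector tensors
    ``{(n_alpha, n_beta): (alpha strings, beta strings, C)}`` with
    ``C[i, j]`` the phase-adjusted coefficient of the determinant with
    up occupation ``alpha[i]`` and down occupation ``beta[j]``."""
    L = state.L
    out = {}
    strings = {n: list(combinations(range(L), n)) for n in range(L + 1)}
    for na in range(L + 1):
        for nb in range(L + 1):
            al, bl = strings[na], strings[nb]
            C = np.zeros((len(al), len(bl)), dtype=state.amplitudes.dtype)
            for i, a in enumerate(al):
                for j, b in enumerate(bl):
                    ks = [0] * L
                    for x in a:
                        ks[x] += 1
                    for x in b:
                        ks[x] += 2
                    idx = DenseState.occupations_to_index(ks)
                    C[i, j] = occupation_phase(a, b) * state.amplitudes[idx]
            if np.any(C != 0):
                out[(na, nb)] = (al, bl, C)
    return out


def _channel_gram(bras, kets, S: np.ndarray) -> np.ndarray:
    """Matrix of Löwdin determinants between two lists of same-size
    occupation tuples."""
    M = np.empty((len(bras), len(kets)))
    for i, b in enumerate(bras):
        for j, k in enumerate(kets):
            if len(b) == 0:
                M[i, j] = 1.0
            else:
                M[i, j] = np.linalg.det(S[np.ix_(b, k)])
    return M


def dense_state_overlap(
    stateX: DenseState, stateY: DenseState, S_XY: np.ndarray
) -> complex:
    """``<Psi^X|Psi^Y>`` for CI vectors over different orbital sets.

    Double sum over determinant pairs weighted by CI coefficients, with
    each determinant pair evaluated by the Löwdin rule; factorizes over
    spin channels within each (n_alpha, n_beta) sector.  Reduces to the
    plain dot product when ``S_XY`` is the identity.
    """
    if stateX.L != stateY.L:
        raise ShapeError("orbital counts differ")
    S = np.asarray(S_XY, dtype=float)
    bx = blocked_amplitudes(stateX)
    by = blocked_amplitudes(stateY)
    total = 0.0 + 0.0j
    for sector, (ax, bxs, CX) in bx.items():
        if sector not in by:
            continue
        ay, bys, CY = by[sector]
        Ma = _channel_gram(ax, ay, S)
        Mb = _channel_gram(bxs, bys, S)
        total += np.einsum("ij,ik,jl,kl->", np.conj(CX), Ma, Mb, CY)
    if stateX.amplitudes.dtype.kind != "c" and stateY.amplitudes.dtype.kind != "c":
        return total.real
    return total


# ---------------------------------------------------------------------------
# dense transition densities and spin-orbit elements
# ---------------------------------------------------------------------------

def dense_tdm(stateA: DenseState, stateB: DenseState, spin_resolved: bool = False):
    """Transition one-particle density by explicit operator action.

    Returns ``D[p, q] = <A|E_pq|B>`` or, with ``spin_resolved``, the array
    ``D[s, t, p, q] = <A|a+_{p,s} a_{q,t}|B>``.
    """
    if stateA.L != stateB.L:
        raise ShapeError("orbital counts differ")
    L = stateA.L
    ca = np.conj(stateA.amplitudes)
    cb = stateB.amplitudes
    if spin_resolved:
        D = np.zeros((2, 2, L, L), dtype=complex)
        for s in (0, 1):
            for t in (0, 1):
                for p in range(L):
                    for q in range(L):
                        D[s, t, p, q] = ca @ (dense_excitation(L, p, q, (s, t)) @ cb)
        return D
    D = np.zeros((L, L), dtype=complex)
    for p in range(L):
        for q in range(L):
            D[p, q] = ca @ (dense_excitation(L, p, q) @ cb)
    return D


# Pauli matrices in the (up, down) basis
_PAULI = {
    "x": np.array([[0, 1], [1, 0]], dtype=complex),
    "y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "z": np.array([[1, 0], [0, -1]], dtype=complex),
}


def dense_soc_hamiltonian(L: int, h_x, h_y, h_z) -> np.ndarray:
    """Dense matrix of the one-electron spin-orbit operator
    ``H_SO = sum_pq sum_k h^k_pq * (1/2) sum_st sigma^k_st a+_ps a_qt``."""
    H = np.zeros((4**L, 4**L), dtype=complex)
    for h, kappa in ((h_x, "x"), (h_y, "y"), (h_z, "z")):
        h = np.asarray(h)
        pauli = _PAULI[kappa]
        for p in range(L):
            for q in range(L):
                if h[p, q] == 0:
                    continue
                for s in (0, 1):
                    for t in (0, 1):
                        if pauli[s, t] == 0:
                            continue
                        op = dense_excitation(L, p, q, (s, t))
                        H += 0.5 * h[p, q] * pauli[s, t] * op.toarray()
    return H


def dense_apply_orbital_rotation(state: DenseState, C: np.ndarray) -> DenseState:
    """Fock-space action of an invertible orbital transformation ``C``.

    Returns the CI vector of the state whose creation operators are
    ``a+_q -> sum_p a+_p C_pq``, computed through the one-body exponential
    ``Gamma(C) = expm(sum_pq logm(C)_pq E_pq)``.  Independent of the
    sequential counter-rotation path, hence usable as its oracle.
    """
    import scipy.linalg

    L = state.L
    K = scipy.linalg.logm(np.asarray(C, dtype=complex))
    gen = np.zeros((4**L, 4**L), dtype=complex)
    for p in range(L):
        for q in range(L):
            if K[p, q] != 0:
                gen += K[p, q] * dense_excitation(L, p, q).toarray()
    amp = scipy.linalg.expm(gen) @ state.amplitudes
    if np.allclose(amp.imag, 0.0, atol=1e-12):
        amp = amp.real
    return DenseState(amp, L)


def _check_spin_labels(state: DenseState, S: float, M: float, tol: float = 1e-8):
    c = state.amplitudes
    n2 = np.vdot(c, c).real
    s2 = np.vdot(c, dense_spin_squared(state.L) @ c).real / n2
    sz = np.vdot(c, dense_sz(state.L) @ c).real / n2
    if abs(s2 - S * (S + 1)) > tol or abs(sz - M) > tol:
        raise SpinPurityError(
            f"state is not an (S={S}, M={M}) eigenstate: "
            f"<S^2>={s2:.2e}, <Sz>={sz:.2e}"
        )


def dense_soc_element(
    stateA: DenseState,
    S_A: float,
    M_A: float,
    stateB: DenseState,
    S_B: float,
    M_B: float,
    soc,
) -> complex:
    """``<A|H_SO|B>`` by explicit dense application; both states must be
    ``S^2``/``Sz`` eigenstates.  ``soc`` provides hartree-scale
    ``h_x, h_y, h_z`` (see :class:`mpssi.state_interaction.SOCIntegrals`)."""
    if stateA.L != stateB.L:
        raise ShapeError("orbital counts differ")
    _check_spin_labels(stateA, S_A, M_A)
    _check_spin_labels(stateB, S_B, M_B)
    hx, hy, hz = soc.in_hartree()
    H = dense_soc_hamiltonian(stateA.L, hx, hy, hz)
    return complex(np.conj(stateA.amplitudes) @ (H @ stateB.amplitudes))
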