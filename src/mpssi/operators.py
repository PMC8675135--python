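"""Second-quantized operators as MPOs over the 4-state orbital basis.

All fermionic phases follow the interleaved spin-orbital order
(1up, 1dn, 2up, 2dn, ...) documented in :mod:`mpssi.core_mps`; each spatial
orbital is a single MPS site, so Jordan-Wigner strings acting on both spin
channels of an intervening site collapse to the site parity
``diag(1, -1, -1, 1)``.
"""

from __future__ import annotations

import numpy as np

from .core_mps import MPO
from .exceptions import ShapeError

__all__ = [
    "excitation_mpo",
    "identity_mpo",
    "one_orbital_rotation_mpo",
    "total_spin_squared_mpo",
    "total_spin_lowering_mpo",
    "mpo_add",
    "A_UP",
    "A_DN",
    "ADAG_UP",
    "ADAG_DN",
    "PARITY",
    "SZ",
    "SPLUS",
    "SMINUS",
    "N_TOT",
    "S2_LOCAL",
]

# single spin-orbital (2x2) blocks
_SM = np.array([[0.0, 1.0], [0.0, 0.0]])  # annihilation
_SP = _SM.T                               # creation
_Z = np.diag([1.0, -1.0])
_I2 = np.eye(2)

# kron(up, dn) enumerates (n_up, n_dn) = (0,0),(0,1),(1,0),(1,1);
# permute into the package order |0>, |up>, |down>, |updown>.
_PERM = np.array([0, 2, 1, 3])


def _site_op(up: np.ndarray, dn: np.ndarray) -> np.ndarray:
    full = np.kron(up, dn)
    return full[np.ix_(_PERM, _PERM)]


A_UP = _site_op(_SM, _I2)          # a_{up}; intra-site order puts up first
A_DN = _site_op(_Z, _SM)           # a_{dn} carries the up-channel JW sign
ADAG_UP = A_UP.T.copy()
ADAG_DN = A_DN.T.copy()
PARITY = _site_op(_Z, _Z)          # full-site JW parity
N_UP = ADAG_UP @ A_UP
N_DN = ADAG_DN @ A_DN
N_TOT = N_UP + N_DN
SZ = 0.5 * (N_UP - N_DN)
SPLUS = ADAG_UP @ A_DN             # S+ = a+_up a_dn (same site, no string)
SMINUS = SPLUS.T.copy()
S2_LOCAL = 0.5 * (SPLUS @ SMINUS + SMINUS @ SPLUS) + SZ @ SZ


def _string_site_ops(L: int, p: int, s: int, q: int, t: int) -> list[np.ndarray]:
    """Per-site 4x4 factors of ``a+_{p,s} a_{q,t}`` (s,t: 0=up, 1=dn).

    Implements the Jordan-Wigner identity: for spin orbitals j < k,
    ``a+_j a_k = sigma+_j Z_{j+1} ... Z_{k-1} sigma-_k`` (and the mirrored
    form for j > k), translated into one 4x4 factor per spatial site.
    """
    j = 2 * p + s  # creation spin orbital
    k = 2 * q + t  # annihilation spin orbital
    slots: list[list[np.ndarray]] = [[_I2.copy(), _I2.copy()] for _ in range(L)]

    def put(so: int, op: np.ndarray) -> None:
        slots[so // 2][so % 2] = slots[so // 2][so % 2] @ op

    if j == k:
        put(j, _SP @ _SM)
    else:
        lo, hi = (j, k) if j < k else (k, j)
        put(lo, _SP if lo == j else _SM)
        put(hi, _SP if hi == j else _SM)
        for so in range(lo + 1, hi):
            put(so, _Z)
    return [_site_op(up, dn) for up, dn in slots]


def _product_mpo(site_ops: list[np.ndarray], coeff: complex = 1.0) -> MPO:
    tensors = [op.reshape(1, 4, 4, 1).astype(np.result_type(op, coeff)) for op in site_ops]
    tensors[0] = tensors[0] * coeff
    return MPO(tensors)


def identity_mpo(L: int) -> MPO:
    return _product_mpo([np.eye(4)] * L)


def mpo_add(a: MPO, b: MPO) -> MPO:
    """Direct sum of two MPOs; op-bond dimensions are additive."""
    if a.L != b.L:
        raise ShapeError(f"site counts differ: {a.L} vs {b.L}")
    L = a.L
    if L == 1:
        return MPO([a.op_tensors[0] + b.op_tensors[0]])
    out = []
    for l in range(L):
        x, y = a.op_tensors[l], b.op_tensors[l]
        if l == 0:
            out.append(np.concatenate([x, y], axis=3))
        elif l == L - 1:
            out.append(np.concatenate([x, y], axis=0))
        else:
            blk = np.zeros(
                (x.shape[0] + y.shape[0], 4, 4, x.shape[3] + y.shape[3]),
                dtype=np.result_type(x, y),
            )
            blk[: x.shape[0], :, :, : x.shape[3]] = x
            blk[x.shape[0] :, :, :, x.shape[3] :] = y
            out.append(blk)
    return MPO(out)


def excitation_mpo(
    p: int,
    q: int,
    L: int,
    spins: tuple[str, str] | None = None,
) -> MPO:
    """One-electron excitation operator as an MPO.

    ``spins=None`` gives the spin-summed singlet excitation
    ``E_pq = sum_sigma a+_{p,sigma} a_{q,sigma}`` (op-bond dimension 2 for
    p != q, 1 on site-diagonal); ``spins=(sigma, tau)`` with entries in
    ``{"up", "down"}`` gives the single spin-resolved string
    ``a+_{p,sigma} a_{q,tau}`` (op-bond dimension 1).  Orbital indices are
    0-based.
    """
    if not (0 <= p < L and 0 <= q < L):
        raise IndexError(f"orbital indices ({p}, {q}) out of range for L={L}")
    idx = {"up": 0, "down": 1}
    if spins is not None:
        s, t = (idx[x] for x in spins)
        return _product_mpo(_string_site_ops(L, p, s, q, t))
    up = _string_site_ops(L, p, 0, q, 0)
    dn = _string_site_ops(L, p, 1, q, 1)
    if p == q:
        merged = [u + d if l == p else u for l, (u, d) in enumerate(zip(up, dn))]
        return _product_mpo(merged)
    return mpo_add(_product_mpo(up), _product_mpo(dn))


def _fsm_mpo(L: int, n_states: int, site_trans, start: int, done: int) -> MPO:
    """Assemble an MPO from a finite-state machine.

    ``site_trans(l)`` returns a dict ``{(from, to): 4x4 op}``; the first
    site keeps only the ``start`` row, the last only the ``done`` column.
    """
    tensors = []
    for l in range(L):
        W = np.zeros((n_states, 4, 4, n_states), dtype=complex)
        for (a, b), op in site_trans(l).items():
            W[a, :, :, b] += op
        if l == 0:
            W = W[start : start + 1]
        if l == L - 1:
            W = W[:, :, :, done : done + 1]
        tensors.append(W)
    # real if possible
    if all(np.allclose(t.imag, 0) for t in tensors):
        tensors = [t.real.copy() for t in tensors]
    return MPO(tensors)


def one_orbital_rotation_mpo(
    L: int, l: int, coeffs: np.ndarray, constant: float = 1.0
) -> MPO:
    """MPO for ``constant * 1 + sum_{p != l} coeffs[p] * E_pl``.

    This is the elementary counter-rotation generator acting on orbital
    ``l`` (all excitations funnel into or out of site ``l``); a four-state
    machine (idle / open up-string / open down-string / finished) realizes
    it with op-bond dimension exactly 4 for any ``L``.
    """
    if not 0 <= l < L:
        raise IndexError(f"orbital {l} out of range for L={L}")
    coeffs = np.asarray(coeffs, dtype=float)
    START, UP, DN, DONE = range(4)

    def trans(s: int) -> dict:
        d = {(START, START): np.eye(4), (DONE, DONE): np.eye(4)}
        if s != l:
            # an open string must terminate at site l: letting it pass
            # through would pair two creations (p < l with p' > l)
            d[(UP, UP)] = PARITY
            d[(DN, DN)] = PARITY
        if s == l:
            d[(START, DONE)] = constant * np.eye(4)
            # open strings toward p > l (annihilate here first)
            d[(START, UP)] = _site_op(_SM, _Z)
            d[(START, DN)] = _site_op(_I2, _SM)
            # close strings from p < l
            d[(UP, DONE)] = _site_op(_SM, _I2)
            d[(DN, DONE)] = _site_op(_Z, _SM)
        elif coeffs[s] != 0.0:
            if s < l:
                d[(START, UP)] = coeffs[s] * _site_op(_SP, _Z)
                d[(START, DN)] = coeffs[s] * _site_op(_I2, _SP)
            else:
                d[(UP, DONE)] = coeffs[s] * _site_op(_SP, _I2)
                d[(DN, DONE)] = coeffs[s] * _site_op(_Z, _SP)
        return d

    return _fsm_mpo(L, 4, trans, START, DONE)


def total_spin_squared_mpo(L: int) -> MPO:
    """MPO for the total spin operator ``S^2 = (sum_i S_i)^2``.

    Uses ``S^2 = sum_i S_i^2 + sum_{i<j} (S+_i S-_j + S-_i S+_j
    + 2 Sz_i Sz_j)``; spin flips pair a creation and an annihilation on the
    same site, so no JW strings appear.  Op-bond dimension 5.
    """
    START, P, M, ZC, DONE = range(5)

    def trans(_s: int) -> dict:
        return {
            (START, START): np.eye(4),
            (DONE, DONE): np.eye(4),
            (START, DONE): S2_LOCAL,
            (START, P): SPLUS,
            (P, P): np.eye(4),
            (P, DONE): SMINUS,
            (START, M): SMINUS,
            (M, M): np.eye(4),
            (M, DONE): SPLUS,
            (START, ZC): 2.0 * SZ,
            (ZC, ZC): np.eye(4),
            (ZC, DONE): SZ,
        }

    return _fsm_mpo(L, 5, trans, START, DONE)


def total_spin_lowering_mpo(L: int) -> MPO:
    """MPO for ``S- = sum_i S-_i`` (op-bond dimension 2)."""
    START, DONE = 0, 1

    def trans(_s: int) -> dict:
        return {
            (START, START): np.eye(4),
            (DONE, DONE): np.eye(4),
            (START, DONE): SMINUS,
        }

    return _fsm_mpo(L, 2, trans, START, DONE)
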