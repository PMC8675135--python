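"""Matrix product states and operators over chains of spatial orbitals.

Each MPS site carries the four-dimensional occupation basis of one spatial
orbital.  The local basis order is fixed package-wide as

    index 0: |0>       (empty)
    index 1: |up>      (one spin-up electron)
    index 2: |down>    (one spin-down electron)
    index 3: |up,down> (doubly occupied)

i.e. ``k = n_up + 2*n_down``, sorted by particle number.  A dense CI vector
over ``L`` orbitals is indexed by the base-4 integer ``sum_l k_l * 4**(L-1-l)``
with site 0 the most significant digit.  The phase convention ties an
occupation string to the ordered product of creation operators

    |k_1 ... k_L> = (a+_{1,up})^{n1u} (a+_{1,dn})^{n1d} ... |vac>,

spin orbitals interleaved as (1up, 1dn, 2up, 2dn, ...); all Jordan-Wigner
sign strings in this package follow that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import MalformedStateError, ResourceLimitError, ShapeError

__all__ = [
    "MPS",
    "MPO",
    "DenseState",
    "mps_from_dense",
    "mps_to_dense",
    "inner",
    "compress",
    "apply_mpo",
    "add",
    "scale",
    "spin_squared_expectation",
    "LOCAL_ORDER",
]

#: Documented local basis order (single source of truth).
LOCAL_ORDER = ("0", "up", "down", "updown")

_LOCAL_DIM = 4
_DENSE_CAP_DEFAULT = 10


@dataclass
class MPS:
    """Matrix product state: one rank-3 tensor per spatial orbital.

    ``site_tensors[l]`` has shape ``(a_{l-1}, 4, a_l)`` with
    ``a_0 = a_L = 1``.  ``log_scale`` is an accumulated real scalar
    prefactor: the represented amplitudes are the tensor contraction
    times ``exp(log_scale)``, so large or tiny global factors (e.g. the
    inactive-orbital scaling of long closed-shell cores) never over- or
    underflow tensor entries.
    """

    site_tensors: list[np.ndarray]
    log_scale: float = 0.0

    def __post_init__(self) -> None:
        if not self.site_tensors:
            raise MalformedStateError("MPS needs at least one site")
        prev = 1
        for l, t in enumerate(self.site_tensors):
            if t.ndim != 3 or t.shape[1] != _LOCAL_DIM:
                raise MalformedStateError(
                    f"site {l}: expected shape (a, 4, b), got {t.shape}"
                )
            if t.shape[0] != prev:
                raise MalformedStateError(
                    f"site {l}: left bond {t.shape[0]} != previous right bond {prev}"
                )
            prev = t.shape[2]
        if prev != 1:
            raise MalformedStateError(f"last right bond must be 1, got {prev}")

    @property
    def L(self) -> int:
        return len(self.site_tensors)

    @property
    def local_dim(self) -> int:
        return _LOCAL_DIM

    @property
    def bond_dims(self) -> list[int]:
        return [1] + [t.shape[2] for t in self.site_tensors]

    def norm_squared(self) -> float:
        return float(np.real(inner(self, self)))

    def copy(self) -> "MPS":
        return MPS([t.copy() for t in self.site_tensors], self.log_scale)


@dataclass
class MPO:
    """Matrix product operator: ``op_tensors[l]`` has shape
    ``(w_{l-1}, k_out, k_in, w_l)`` with ``w_0 = w_L = 1``."""

    op_tensors: list[np.ndarray]

    def __post_init__(self) -> None:
        prev = 1
        for l, t in enumerate(self.op_tensors):
            if t.ndim != 4 or t.shape[1] != _LOCAL_DIM or t.shape[2] != _LOCAL_DIM:
                raise MalformedStateError(
                    f"op site {l}: expected shape (w, 4, 4, v), got {t.shape}"
                )
            if t.shape[0] != prev:
                raise MalformedStateError(
                    f"op site {l}: left bond {t.shape[0]} != previous right bond {prev}"
                )
            prev = t.shape[3]
        if prev != 1:
            raise MalformedStateError("last op bond must be 1")

    @property
    def L(self) -> int:
        return len(self.op_tensors)

    @property
    def bond_dims(self) -> list[int]:
        return [1] + [t.shape[3] for t in self.op_tensors]

    @property
    def max_bond_dim(self) -> int:
        return max(self.bond_dims)


@dataclass
class DenseState:
    """Full CI vector over the ``4**L`` occupation strings."""

    amplitudes: np.ndarray
    L: int = field(default=0)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes)
        if self.amplitudes.ndim != 1:
            raise MalformedStateError("amplitudes must be one-dimensional")
        n = self.amplitudes.size
        if self.L == 0:
            L = round(math.log(n, 4)) if n > 0 else -1
            if L < 1 or 4**L != n:
                raise MalformedStateError(
                    f"amplitude vector length {n} is not a power of 4"
                )
            self.L = L
        elif 4**self.L != n:
            raise MalformedStateError(
                f"length {n} inconsistent with L={self.L}"
            )
        if not np.all(np.isfinite(self.amplitudes)):
            raise MalformedStateError("non-finite amplitudes")

    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    @staticmethod
    def index_to_occupations(index: int, L: int) -> tuple[int, ...]:
        """Base-4 digits ``(k_1, ..., k_L)`` of a dense index."""
        return tuple((index // 4 ** (L - 1 - l)) % 4 for l in range(L))

    @staticmethod
    def occupations_to_index(ks) -> int:
        L = len(ks)
        return int(sum(int(k) * 4 ** (L - 1 - l) for l, k in enumerate(ks)))


def mps_from_dense(state: DenseState, tol: float = 0.0) -> MPS:
    """Factor a dense CI vector into an MPS by repeated SVD, left to right.

    Singular values below ``tol`` times the largest at each bond are
    discarded; numerically vanishing ones (below 1e-14 relative) are always
    dropped, so ``tol = 0`` keeps the exact Schmidt rank -- product states
    factor to bond dimension 1 and the round-trip error stays at machine
    precision.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    v = np.asarray(state.amplitudes)
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise MalformedStateError(
            "zero state has no meaningful Schmidt decomposition"
        )
    L = state.L
    tensors: list[np.ndarray] = []
    rest = v.reshape(1, -1)
    for _ in range(L - 1):
        a = rest.shape[0]
        mat = rest.reshape(a * _LOCAL_DIM, -1)
        u, s, vt = np.linalg.svd(mat, full_matrices=False)
        if s[0] > 0:
            keep = int(np.sum(s >= max(tol, 1e-14) * s[0]))
        else:
            keep = 1
        keep = max(keep, 1)
        tensors.append(u[:, :keep].reshape(a, _LOCAL_DIM, keep))
        rest = (s[:keep, None] * vt[:keep])
    tensors.append(rest.reshape(rest.shape[0], _LOCAL_DIM, 1))
    return MPS(tensors)


def mps_to_dense(psi: MPS, cap: int = _DENSE_CAP_DEFAULT) -> DenseState:
    """Contract an MPS to a dense CI vector (memory-bounded by ``cap``)."""
    if psi.L > cap:
        raise ResourceLimitError(
            f"L={psi.L} exceeds dense-expansion cap {cap}"
        )
    res = psi.site_tensors[0].reshape(_LOCAL_DIM, -1)
    for t in psi.site_tensors[1:]:
        res = np.einsum("ia,akb->ikb", res, t).reshape(res.shape[0] * _LOCAL_DIM, -1)
    amp = res[:, 0] * math.exp(psi.log_scale)
    return DenseState(amp, psi.L)


def inner(bra: MPS, ket: MPS) -> complex:
    """``<bra|ket>`` by transfer-matrix contraction (bra is conjugated)."""
    if bra.L != ket.L:
        raise ShapeError(f"site counts differ: {bra.L} vs {ket.L}")
    env = np.ones((1, 1))
    for tb, tk in zip(bra.site_tensors, ket.site_tensors):
        env = np.einsum("ab,akc,bkd->cd", env, np.conj(tb), tk)
    return complex(env[0, 0]) * math.exp(bra.log_scale + ket.log_scale)


def scale(psi: MPS, factor: complex) -> MPS:
    """Multiply all amplitudes by ``factor``.

    The magnitude goes into ``log_scale``; the sign/phase is absorbed into
    the first site tensor so tensor entries stay well-conditioned.
    """
    if not np.isfinite(factor):
        raise ValueError("scale factor must be finite")
    out = psi.copy()
    if factor == 0:
        out.site_tensors[0] = np.zeros_like(out.site_tensors[0])
        return out
    mag = abs(factor)
    out.site_tensors[0] = out.site_tensors[0] * (factor / mag)
    out.log_scale += math.log(mag)
    return out


def add(a: MPS, b: MPS) -> MPS:
    """Amplitude-wise sum; bond dimensions are additive at internal bonds."""
    if a.L != b.L:
        raise ShapeError(f"site counts differ: {a.L} vs {b.L}")
    ref = max(a.log_scale, b.log_scale)
    fa = math.exp(a.log_scale - ref)
    fb = math.exp(b.log_scale - ref)
    ta = [t.copy() for t in a.site_tensors]
    tb = [t.copy() for t in b.site_tensors]
    ta[0] = ta[0] * fa
    tb[0] = tb[0] * fb
    L = a.L
    if L == 1:
        return MPS([ta[0] + tb[0]], ref)
    out: list[np.ndarray] = []
    for l in range(L):
        x, y = ta[l], tb[l]
        if l == 0:
            out.append(np.concatenate([x, y], axis=2))
        elif l == L - 1:
            out.append(np.concatenate([x, y], axis=0))
        else:
            blk = np.zeros(
                (x.shape[0] + y.shape[0], _LOCAL_DIM, x.shape[2] + y.shape[2]),
                dtype=np.result_type(x, y),
            )
            blk[: x.shape[0], :, : x.shape[2]] = x
            blk[x.shape[0] :, :, x.shape[2] :] = y
            out.append(blk)
    return MPS(out, ref)


def apply_mpo(op: MPO, psi: MPS) -> MPS:
    """Apply an MPO; output bond dimensions are products ``w_l * a_l``."""
    if op.L != psi.L:
        raise ShapeError(f"site counts differ: {op.L} vs {psi.L}")
    out = []
    for w, m in zip(op.op_tensors, psi.site_tensors):
        t = np.einsum("wxkv,akb->waxvb", w, m)
        out.append(
            t.reshape(w.shape[0] * m.shape[0], _LOCAL_DIM, w.shape[3] * m.shape[2])
        )
    return MPS(out, psi.log_scale)


def compress(psi: MPS, m: int, tol: float = 0.0) -> tuple[MPS, float]:
    """SVD-truncate every bond to dimension at most ``m``.

    The state is first brought to left-canonical form (QR sweep), then a
    right-to-left SVD sweep truncates, so the discarded weight -- the sum of
    the discarded squared singular values over all bonds, reported on the
    scale of the state's true squared norm -- is well defined.  The output
    is *not* renormalized: overlap magnitudes are the product of interest
    and silently restoring the norm would bias them.  Singular values below
    ``tol`` times the bond's largest are dropped as well.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    L = psi.L
    tensors = [t.copy() for t in psi.site_tensors]
    # left-canonicalizing sweep
    for l in range(L - 1):
        a, d, b = tensors[l].shape
        q, r = np.linalg.qr(tensors[l].reshape(a * d, b))
        tensors[l] = q.reshape(a, d, q.shape[1])
        tensors[l + 1] = np.einsum("ij,jkl->ikl", r, tensors[l + 1])
    # truncating sweep, right to left
    discarded = 0.0
    for l in range(L - 1, 0, -1):
        a, d, b = tensors[l].shape
        u, s, vt = np.linalg.svd(tensors[l].reshape(a, d * b), full_matrices=False)
        if s.size and s[0] > 0 and tol > 0:
            keep = int(np.sum(s >= tol * s[0]))
        else:
            keep = s.size
        keep = max(1, min(m, keep))
        discarded += float(np.sum(s[keep:] ** 2))
        tensors[l] = vt[:keep].reshape(keep, d, b)
        carry = u[:, :keep] * s[:keep]
        tensors[l - 1] = np.einsum("ijk,kl->ijl", tensors[l - 1], carry)
    return MPS(tensors, psi.log_scale), discarded * math.exp(2.0 * psi.log_scale)


def spin_squared_expectation(psi: MPS) -> float:
    """``<S^2>`` normalized by ``<psi|psi>``; equals S(S+1) for spin
    eigenstates regardless of normalization."""
    from .operators import total_spin_squared_mpo

    n2 = psi.norm_squared()
    if n2 <= 0.0:
        raise MalformedStateError("spin expectation undefined for zero-norm state")
    val = inner(psi, apply_mpo(total_spin_squared_mpo(psi.L), psi))
    return float(np.real(val)) / n2
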