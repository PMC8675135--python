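"""Sequential MPS counter-rotation into a biorthonormal orbital basis.

The transformation runs over the active orbitals in ascending order; for
orbital ``l`` it

1. scales the local tensor slices by ``t_ll`` per electron in orbital
   ``l`` (``t_ll**2`` for the doubly occupied slice, ``t_ll`` for the
   singly occupied ones),
2. applies the excitation operator built from the off-diagonal/diagonal
   ratios ``that_l = sum_{p != l} (t_pl / t_ll) E_pl``:
   the *full* scheme realizes ``1 + that_l + that_l**2 / 2`` -- exact,
   since three or more excitations out of one orbital vanish -- through
   two sequential applications of ``that_l`` with an intermediate SVD
   compression, adding the three resulting MPSs; the *approximate* scheme
   keeps only ``1 + that_l``, which is accurate to second order in the
   deviation of t from the identity,
3. SVD-compresses the result back to the configured bond dimension.

The inactive (doubly occupied) orbitals contribute only the scalar
prefactor ``alpha``, applied once into the MPS ``log_scale``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .biortho import DEFAULT_CUTOFF, CounterRotationData
from .core_mps import MPS, add, apply_mpo, compress, scale, spin_squared_expectation
from .exceptions import ConfigError, ShapeError
from .operators import one_orbital_rotation_mpo

__all__ = [
    "RotationPlan",
    "TransformedState",
    "site_scale",
    "build_rotation_mpo",
    "counter_rotate",
]


@dataclass
class RotationPlan:
    """Configuration of one counter-rotation run.

    ``m_compress`` defaults (via :func:`counter_rotate`) to the input
    state's maximum bond dimension -- the economical choice of compressing
    back to the original m.  ``per_site_report`` is filled during the run
    with ``(orbital, pre bond dims, post bond dims, discarded_weight)``
    records.
    """

    mode: str = "full"
    m_compress: int | None = None
    svd_tol: float = 0.0
    cutoff: float = DEFAULT_CUTOFF
    per_site_report: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("full", "approximate"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.m_compress is not None and self.m_compress < 1:
            raise ConfigError("m_compress must be >= 1")
        if self.svd_tol < 0:
            raise ConfigError("svd_tol must be non-negative")


@dataclass
class TransformedState:
    """Counter-rotated MPS plus the accuracy monitors of the run."""

    psi_out: MPS
    total_discarded_weight: float
    spin_sq_before: float
    spin_sq_after: float
    deviation_norm_used: float


def site_scale(psi: MPS, l: int, t_ll: float) -> MPS:
    """Occupation scaling of orbital ``l``: slice ``|updown>`` by
    ``t_ll**2``, ``|up>`` and ``|down>`` by ``t_ll``, ``|0>`` untouched."""
    if not 0 <= l < psi.L:
        raise IndexError(f"orbital {l} out of range for L={psi.L}")
    out = psi.copy()
    tens = out.site_tensors[l].copy()
    tens[:, 1, :] *= t_ll
    tens[:, 2, :] *= t_ll
    tens[:, 3, :] *= t_ll * t_ll
    out.site_tensors[l] = tens
    return out


def build_rotation_mpo(t: np.ndarray, l: int, order: str = "linear"):
    """Rotation MPO for active orbital ``l`` of the active-block matrix t.

    ``order="linear"`` returns ``1 + that_l``; ``order="quadratic-term"``
    returns the bare generator ``that_l``, whose sequential double
    application supplies the second-order term of the full scheme.  Both
    have op-bond dimension 4 (idle / up string / down string / finished).
    """
    t = np.asarray(t)
    L = t.shape[0]
    if t.shape != (L, L):
        raise ShapeError("t must be square")
    if t[l, l] == 0:
        raise ConfigError(f"zero diagonal t element at orbital {l}")
    if order not in ("linear", "quadratic-term"):
        raise ConfigError(f"unknown rotation-operator order {order!r}")
    coeffs = t[:, l] / t[l, l]
    coeffs[l] = 0.0
    constant = 1.0 if order == "linear" else 0.0
    return one_orbital_rotation_mpo(L, l, coeffs, constant=constant)


def counter_rotate(
    psi: MPS, rot: CounterRotationData, plan: RotationPlan | None = None
) -> TransformedState:
    """Transform an MPS into the biorthonormal orbital basis.

    ``psi`` lives on the active orbitals only; ``rot`` supplies the t
    matrix (full inactive+active), the inactive scalar ``alpha`` and the
    deviation norm.  With exact compression (``m_compress`` at least the
    attainable Schmidt rank, ``svd_tol = 0``) the full mode reproduces the
    exact representation of the input state in the transformed basis.
    """
    plan = plan if plan is not None else RotationPlan()
    t_act = np.asarray(rot.t)[rot.active_slice, rot.active_slice]
    L = t_act.shape[0]
    if psi.L != L:
        raise ShapeError(
            f"state has {psi.L} sites but t has {L} active orbitals"
        )
    m = plan.m_compress if plan.m_compress is not None else max(psi.bond_dims)
    if rot.deviation_norm >= plan.cutoff and plan.mode == "approximate":
        warnings.warn(
            f"deviation norm {rot.deviation_norm:.3f} is at or above the "
            f"cutoff {plan.cutoff}; the linearized counter-rotation may be "
            "inaccurate -- consider mode='full'",
            stacklevel=2,
        )
    plan.per_site_report.clear()
    spin_before = spin_squared_expectation(psi)
    state = scale(psi, rot.alpha)
    total_discarded = 0.0
    for l in range(L):
        pre_bonds = list(state.bond_dims)
        state = site_scale(state, l, t_act[l, l])
        if plan.mode == "approximate":
            op = build_rotation_mpo(t_act, l, order="linear")
            state = apply_mpo(op, state)
            state, w = compress(state, m, plan.svd_tol)
            total_discarded += w
        else:
            gen = build_rotation_mpo(t_act, l, order="quadratic-term")
            first = apply_mpo(gen, state)
            first, w1 = compress(first, m, plan.svd_tol)
            second = apply_mpo(gen, first)
            second, w2 = compress(second, m, plan.svd_tol)
            state = add(add(state, first), scale(second, 0.5))
            state, w3 = compress(state, m, plan.svd_tol)
            total_discarded += w1 + w2 + w3
        plan.per_site_report.append(
            (l, pre_bonds, list(state.bond_dims), total_discarded)
        )
    spin_after = spin_squared_expectation(state)
    return TransformedState(
        psi_out=state,
        total_discarded_weight=total_discarded,
        spin_sq_before=spin_before,
        spin_sq_after=spin_after,
        deviation_norm_used=rot.deviation_norm,
    )
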