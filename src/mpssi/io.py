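"""File formats: whitespace-delimited text matrices, HDF5 tensors, and the
fixture bundle container.

Orbital indices are 1-based in every file and report; the conversion to the
0-based internal convention happens here and only here.  The exact HDF5
layouts are documented in ``docs/file_formats.md``.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .biortho import OrbitalBasisPair
from .core_mps import MPS, LOCAL_ORDER
from .exceptions import FileFormatError, ShapeError
from .state_interaction import SOCIntegrals

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_mps",
    "load_mps",
    "save_bundle",
    "load_bundle",
]

_H5_SUFFIXES = (".h5", ".hdf5")


def _split_h5_path(path: str):
    for suf in _H5_SUFFIXES:
        marker = suf + ":"
        if marker in path:
            fname, dset = path.split(marker, 1)
            return fname + suf, dset
        if path.endswith(suf):
            return path, None
    return None, None


def read_matrix(path: str, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a matrix from a text file or an HDF5 dataset.

    HDF5 paths may name the dataset as ``file.h5:group/dset`` (default
    dataset: ``matrix``).  Text files are whitespace-delimited, ``#``
    starts a comment; ragged rows raise a :class:`FileFormatError` naming
    the offending line.
    """
    fname, dset = _split_h5_path(path)
    if fname is not None:
        if not os.path.exists(fname):
            raise FileFormatError(f"{fname}: no such file")
        with h5py.File(fname, "r") as f:
            key = dset or "matrix"
            if key not in f:
                raise FileFormatError(f"{fname}: no dataset {key!r}")
            M = np.asarray(f[key])
    else:
        if not os.path.exists(path):
            raise FileFormatError(f"{path}: no such file")
        rows = []
        width = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                body = line.split("#", 1)[0].strip()
                if not body:
                    continue
                try:
                    row = [complex(tok) for tok in body.split()]
                except ValueError as exc:
                    raise FileFormatError(
                        f"{path}:{lineno}: cannot parse {body!r}"
                    ) from exc
                if width is None:
                    width = len(row)
                elif len(row) != width:
                    raise FileFormatError(
                        f"{path}:{lineno}: row has {len(row)} entries, "
                        f"expected {width}"
                    )
                rows.append(row)
        if not rows:
            raise FileFormatError(f"{path}: empty matrix file")
        M = np.array(rows)
        if np.allclose(M.imag, 0.0):
            M = M.real
    if expected_shape is not None and M.shape != tuple(expected_shape):
        raise ShapeError(
            f"{path}: expected shape {tuple(expected_shape)}, got {M.shape}"
        )
    return M


def write_matrix(path: str, M: np.ndarray) -> None:
    """Write a matrix as text (or as HDF5 when the path says so)."""
    M = np.asarray(M)
    fname, dset = _split_h5_path(path)
    if fname is not None:
        with h5py.File(fname, "a") as f:
            key = dset or "matrix"
            if key in f:
                del f[key]
            f.create_dataset(key, data=M)
        return
    with open(path, "w") as fh:
        for row in np.atleast_2d(M):
            fh.write(" ".join(repr(complex(x)) if np.iscomplexobj(M) else f"{x:.17g}"
                              for x in row))
            fh.write("\n")


def save_mps(group: h5py.Group, psi: MPS) -> None:
    """MPS container layout: datasets ``site_0 ... site_{L-1}`` of shape
    ``(a_{l-1}, 4, a_l)``, attributes ``L``, ``local_order`` and
    ``log_scale``."""
    for l, t in enumerate(psi.site_tensors):
        group.create_dataset(f"site_{l}", data=t)
    group.attrs["L"] = psi.L
    group.attrs["local_order"] = ",".join(LOCAL_ORDER)
    group.attrs["log_scale"] = psi.log_scale


def load_mps(group: h5py.Group) -> MPS:
    L = int(group.attrs["L"])
    order = str(group.attrs.get("local_order", ""))
    if order and order != ",".join(LOCAL_ORDER):
        raise FileFormatError(
            f"unsupported local basis order {order!r}; this package uses "
            + ",".join(LOCAL_ORDER)
        )
    tensors = [np.asarray(group[f"site_{l}"]) for l in range(L)]
    return MPS(tensors, float(group.attrs.get("log_scale", 0.0)))


def save_bundle(
    path: str,
    pair: OrbitalBasisPair,
    states_X,
    states_Y,
    soc: SOCIntegrals | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a complete fixture bundle.

    ``states_X`` / ``states_Y`` are sequences of ``(mps, S, M, energy)``
    tuples attached to the X and Y orbital sets respectively.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("orbitals")
        g.create_dataset("C_X", data=pair.C_X)
        g.create_dataset("C_Y", data=pair.C_Y)
        g.create_dataset("S_AO", data=pair.S_AO)
        g.attrs["n_inactive"] = pair.n_inactive
        g.attrs["n_active"] = pair.n_active
        for name, states in (("states_X", states_X), ("states_Y", states_Y)):
            sg = f.create_group(name)
            sg.attrs["n_states"] = len(states)
            for i, (psi, S, M, E) in enumerate(states):
                st = sg.create_group(f"state_{i}")
                save_mps(st, psi)
                st.attrs["S"] = S
                st.attrs["M"] = M
                st.attrs["energy"] = E
        if soc is not None:
            sg = f.create_group("soc")
            sg.create_dataset("h_x", data=soc.h_x)
            sg.create_dataset("h_y", data=soc.h_y)
            sg.create_dataset("h_z", data=soc.h_z)
            sg.attrs["unit"] = soc.unit
        if metadata:
            mg = f.create_group("metadata")
            for k, v in metadata.items():
                mg.attrs[k] = v


def load_bundle(path: str) -> dict:
    """Read a fixture bundle back into in-memory objects."""
    if not os.path.exists(path):
        raise FileFormatError(f"{path}: no such file")
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "orbitals" not in f:
            raise FileFormatError(f"{path}: missing 'orbitals' group")
        g = f["orbitals"]
        out["pair"] = OrbitalBasisPair(
            C_X=np.asarray(g["C_X"]),
            C_Y=np.asarray(g["C_Y"]),
            S_AO=np.asarray(g["S_AO"]),
            n_inactive=int(g.attrs["n_inactive"]),
            n_active=int(g.attrs["n_active"]),
        )
        for name in ("states_X", "states_Y"):
            states = []
            if name in f:
                sg = f[name]
                for i in range(int(sg.attrs["n_states"])):
                    st = sg[f"state_{i}"]
                    states.append(
                        (
                            load_mps(st),
                            float(st.attrs["S"]),
                            float(st.attrs["M"]),
                            float(st.attrs["energy"]),
                        )
                    )
            out[name] = states
        out["soc"] = None
        if "soc" in f:
            sg = f["soc"]
            out["soc"] = SOCIntegrals(
                h_x=np.asarray(sg["h_x"]),
                h_y=np.asarray(sg["h_y"]),
                h_z=np.asarray(sg["h_z"]),
                unit=str(sg.attrs.get("unit", "hartree")),
            )
        out["metadata"] = (
            dict(f["metadata"].attrs) if "metadata" in f else {}
        )
    return out
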