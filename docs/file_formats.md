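# File formats

All orbital indices in files and reports are 1-based; the in-memory API is
0-based.  Text matrices are whitespace-delimited, `#` starts a comment.
HDF5 paths may address a dataset as `file.h5:group/name` (default dataset
name: `matrix`).

## MPS container (HDF5 group)

| entry | meaning |
| --- | --- |
| `site_0` … `site_{L-1}` | rank-3 arrays, shape `(a_{l-1}, 4, a_l)`, real or complex; `a_0 = a_L = 1` |
| attr `L` | number of spatial-orbital sites |
| attr `local_order` | `"0,up,down,updown"` — the fixed local basis order |
| attr `log_scale` | real scalar; amplitudes are the contraction times `exp(log_scale)` |

## Fixture bundle (HDF5 file)

```
orbitals/
    C_X        (n_AO, L_tot)  MO coefficients of basis X
    C_Y        (n_AO, L_tot)  MO coefficients of basis Y
    S_AO       (n_AO, n_AO)   AO overlap (symmetric positive definite)
    @n_inactive, @n_active    L_tot = n_inactive + n_active; inactive
                              columns first; virtuals excluded
states_X/                     states attached to basis X
    @n_states
    state_0/ … state_{n-1}/   MPS container (above) plus attrs
        @S, @M, @energy       spin labels and spin-free energy (hartree)
states_Y/                     same layout, attached to basis Y
soc/                          optional
    h_x, h_y, h_z             (n_active, n_active) complex, Hermitian,
                              purely imaginary, zero diagonal
    @unit                     "hartree" or "cm-1"
metadata/                     optional free-form attributes
```

SOC integrals refer to the active orbitals of the orthonormal reference
in which `C_X`/`C_Y` are expressed (see `docs/methods.md`).

## JSON report

Produced by `mpssi transform|overlap|soc --report out.json` and by
`mpssi.pipeline.run_pipeline`.  Deterministic for identical inputs up to
the `timestamp` field.  Top-level keys:

* `config` — the effective run configuration, echoed verbatim.
* `diagnostics` — `deviation_norm` (and per side), the norm definition,
  `cutoff`, `exceeds_cutoff`, `recommended_mode`, `alpha_bra/ket`,
  `inactive_active_mixing`.
* `transform` — per-state, per-site records: bond dimensions before and
  after, cumulative discarded weight, ⟨S²⟩ before/after, warnings.
* `overlap.cross` — the matrix ⟨X_i|Y_j⟩.
* `oracle_check` — max/mean deviation from the dense Löwdin contraction
  (only when requested and the active space is small enough, L ≤ 6).
* `soc` — state labels, |SOC| in cm⁻¹, the complex SOC matrix in
  hartree (`re`/`im` pairs), the union overlap metric, spin-free and
  spin-orbit corrected energies (hartree and cm⁻¹).

Complex arrays are serialized as `{"re": [...], "im": [...]}`.
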