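# mpssi

State interaction for matrix product state (MPS) wave functions expressed in
**nonorthogonal molecular-orbital bases**.

Multiconfigurational electronic-structure calculations — CASSCF or its DMRG
variant — optimize each spin manifold (or each molecular geometry) in its own
set of molecular orbitals.  Computing couplings *between* such states —
wave-function overlaps for nonadiabatic dynamics, spin–orbit coupling (SOC)
matrix elements for heavy-element photochemistry, spin–orbit corrected
energies — then requires matrix elements between determinant expansions over
two mutually nonorthogonal orbital sets.  Done naively this costs a
factorial-scaling nonorthogonal CI contraction.  The state-interaction route
avoids it by transforming both states into a **biorthonormal** pair of
orbital bases, ⟨φ<sub>p</sub><sup>A</sup>|φ<sub>q</sub><sup>B</sup>⟩ =
δ<sub>pq</sub>, after which every cross matrix element reduces to a plain
coefficient contraction.

This package implements that route for MPS wave functions:

1. **Biorthonormalization.** From the MO cross-overlap
   S<sup>XY</sup> = C<sub>X</sub>ᵀ S<sub>AO</sub> C<sub>Y</sub>, an unpivoted
   LU factorization of (S<sup>XY</sup>)⁻¹ yields triangular transformation
   matrices C<sup>XA</sup>, C<sup>YB</sup> with
   (C<sup>XA</sup>)ᵀ S<sup>XY</sup> C<sup>YB</sup> = I.
2. **Counter-rotation.** The CI coefficients must co-transform.  From the LU
   factors of C<sup>XA</sup> a matrix **t** is assembled; looping over the
   active orbitals *l* in ascending order, the MPS is updated by scaling the
   local occupations with t<sub>ll</sub> per electron and applying
   1 + t̂<sub>l</sub> + ½t̂<sub>l</sub>², where
   t̂<sub>l</sub> = Σ<sub>p≠l</sub> (t<sub>pl</sub>/t<sub>ll</sub>) E<sub>pl</sub>.
   Because an orbital holds at most two electrons, t̂<sub>l</sub>³ ≡ 0 and
   this operator is *exact* ("full" mode).  Doubly occupied inactive orbitals
   enter through a single scalar α = Π<sub>i</sub> t<sub>ii</sub>².
3. **Linearized scheme.**  Dropping the second-order ½t̂² term ("approximate"
   mode) removes one MPO application and one SVD compression per orbital; the
   error is second order in the deviation of **t** from the identity.  The
   Frobenius norm ‖t − I<sub>L</sub>‖ is therefore an **a-priori accuracy
   diagnostic**, with a conservative cutoff of 1 below which the linearized
   scheme is recommended.
4. **State interaction.**  Overlap matrices, one-particle transition
   densities D<sub>pq</sub> = ⟨A|E<sub>pq</sub>|B⟩, SOC matrices from
   one-electron spin–orbit integrals contracted with spin-resolved transition
   densities, and spin–orbit corrected energies from the generalized
   eigenproblem over the (possibly nonorthogonal) state basis.

Every stage is testable without external quantum-chemistry data: a dense-CI
oracle (generalized Löwdin determinant rule, explicit second quantization)
provides ground truth, and synthetic generators supply orbital pairs with a
tunable rotation magnitude θ, spin-pure Hubbard-chain eigenstates, and random
Hermitian purely imaginary SOC integrals.

## Worked example

Generate a synthetic fixture — three active orbitals, four electrons, two
singlets in orbital basis X and two triplets in a basis Y rotated by
θ = 0.2 — then inspect the diagnostic and run the SOC workflow:

```sh
$ mpssi synth --l-active 3 --n-elec 4 --theta 0.2 \
        --n-singlets 2 --n-triplets 2 --seed 3 --out demo.h5
wrote bundle: demo.h5

$ mpssi diagnose --bundle demo.h5
deviation norm (bra side, X->A): 0.143021
deviation norm (ket side, Y->B): 0.142431
cutoff: 1.0
below cutoff: linearized counter-rotation is adequate
```

The deviation norm ‖t − I‖ ≈ 0.14 is far below the cutoff of 1, so the
cheap linearized counter-rotation is safe for this pair of orbital sets.

```sh
$ mpssi soc --bundle demo.h5
deviation norm 0.143021 (cutoff 1.0, exceeds: False)
state pair |SOC| (cm-1):
  X(S=0.0,M=0.0) | Y(S=1.0,M=1.0): 17.7748
  X(S=0.0,M=0.0) | Y(S=1.0,M=0.0): 25.7264
  X(S=0.0,M=0.0) | Y(S=1.0,M=-1.0): 17.7748
  ...
spin-orbit corrected energies (cm-1, relative):
  state 1: 0.0000
  state 2: 128565.2725
  state 3: 128565.2727
  state 4: 128565.2831
  ...
```

The table lists |⟨S M|Ĥ<sub>SO</sub>|S′ M′⟩| between every multiplet
component (here singlet–triplet couplings of a few tens of cm⁻¹, set by the
synthetic integral scale), and the corrected energies show the triplet
splitting of ~0.01 cm⁻¹ induced by the SOC on top of the spin-free gaps.
Adding `--check-against-oracle` to `mpssi overlap` on systems this small
verifies the whole chain against the dense Löwdin-rule contraction
(agreement to ~1e−16).

A Python session gives finer control; see `mpssi.counter_rotate`,
`mpssi.soc_matrix`, `mpssi.si_eigensolve` and `mpssi.build_scan`.

## Layout

| module | contents |
| --- | --- |
| `mpssi.core_mps` | MPS/MPO/dense-state containers, SVD factorization, compression, MPO application |
| `mpssi.operators` | second-quantized operators as MPOs (excitations, Ŝ², Ŝ⁻) with Jordan–Wigner phases |
| `mpssi.biortho` | biorthonormalization, the t matrix, α, the deviation-norm diagnostic |
| `mpssi.counterrotate` | the sequential counter-rotation, full and linearized |
| `mpssi.oracle` | dense-CI ground truth (Löwdin rule, densities, SOC elements) |
| `mpssi.state_interaction` | overlap/TDM/SOC assembly and the SI eigensolve |
| `mpssi.synthetic` | deterministic generators for orbitals, states, integrals, scans |
| `mpssi.io`, `mpssi.pipeline`, `mpssi.cli` | file formats, orchestration, command line |

File formats are documented in `docs/file_formats.md`, the scientific and
numerical choices in `docs/methods.md`.
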