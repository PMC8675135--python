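# Methods

This note records the model, the algorithmic and numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Wave-function model

States are matrix product states over the active spatial orbitals: one
rank-3 tensor per orbital with the four-dimensional local basis
(|0⟩, |↑⟩, |↓⟩, |↑↓⟩), ordered by particle number, `k = n_up + 2·n_dn`.
A dense CI vector over L orbitals is indexed by the base-4 integer with
site 1 most significant.  The phase convention fixes an occupation string
as the product of creation operators in site order, ↑ before ↓ within a
site; equivalently, spin orbitals are interleaved as (1↑, 1↓, 2↑, 2↓, …)
and all Jordan–Wigner strings follow that order.  Keeping both spin
channels of an orbital on one site means a string passing through a site
contributes the site parity diag(1, −1, −1, 1), and each spatial orbital
remains a single MPS site.  Tensors are dense, without quantum-number
block structure: at the desk scale this package targets (L ≤ 10),
symmetry blocking is unnecessary engineering; particle-number and
S<sub>z</sub> conservation are instead asserted in tests.  A real
`log_scale` attribute carries global scalar prefactors (notably the
inactive-orbital factor α) so that long closed-shell cores can never
underflow tensor entries.

## Biorthonormal transformation and the t matrix

Given orthonormal MO sets X and Y over a shared AO basis, the cross
overlap is S^XY = C_Xᵀ S_AO C_Y over the inactive + active columns
(virtuals never enter the wave function and are dropped first).  An
**unpivoted** LU factorization (S^XY)⁻¹ = L·U (L unit lower) defines
C^YB = L and C^XA = Uᵀ, which satisfy (C^XA)ᵀ S^XY C^YB = I exactly and
are both lower triangular.  Pivoting is deliberately excluded: the
orbital-by-orbital structure of the sequential counter-rotation depends
on the triangular factors being in orbital order.  A pivot below 1e−12
aborts with the 1-based index of the failing orbital; reordering orbitals
is left to the caller.

The counter-rotation driver is assembled from the unpivoted LU factors
C = C_L C_U (C_L unit lower) of a transformation matrix C:

    t = inv(C_U)  (upper triangle including the diagonal)
      + strict_lower(−C_L).

Looping over orbitals l = 1…L in ascending order and applying, per
orbital, the occupation scaling t_ll per electron followed by
1 + t̂_l + ½t̂_l² with t̂_l = Σ_{p≠l} (t_pl/t_ll) E_pl, reproduces the
exact re-expression of the CI vector generated by C⁻¹.  Two facts make
this work: (i) the operator product for one orbital implements an
elementary column transformation of the creation operators, and the
descending elimination of C⁻¹ into such elementary columns exists in
closed form through the LU factors as above; (ii) t̂_l³ ≡ 0, because three
excitations out of one spatial orbital annihilate any state, so the
quadratic Taylor form of exp(t̂_l) is already exact.  Both facts are
enforced numerically: the package-level contract is that full-mode
counter-rotation at exact bond dimension reproduces the dense
Löwdin-rule overlap to better than 1e−8 (in practice it is machine
precision), and this is the primary correctness surface of the test
suite.

Inactive (doubly occupied) orbitals contribute the scalar
α = Π_i t_ii², applied once into `log_scale`.  This is exact when the
transformation does not mix the inactive and active spaces: every
excitation into a closed-shell orbital is Pauli-blocked, and excitations
out of the core are exactly the neglected mixing.  The largest |t|
element in the inactive–active off-diagonal blocks is computed and a
warning is emitted above 1e−6; no correction is attempted.  Note that α
departs from 1 only when the retained orbital spaces are truncated
(virtuals dropped) — for complete orthonormal sets the inactive block of
S^XY is orthogonal and α = 1 identically; the frozen-core test therefore
rotates inactive orbitals into a discarded virtual.

## Full vs linearized scheme, and the a-priori diagnostic

The *full* scheme realizes 1 + t̂ + ½t̂² by applying the bare generator t̂
twice, with an SVD compression between the applications, and summing the
three MPSs.  The *approximate* scheme keeps 1 + t̂ only.  Since
t_pl/t_ll → 0 as the orbital sets approach each other, the neglected term
is second order in the deviation of t from the identity, which the scan
tests confirm with a log–log slope of ≈ 2 of the overlap error in the
rotation magnitude.

The Frobenius norm ‖t − I_L‖ over the active block is the a-priori
accuracy measure ("L2 norm" is read entrywise; the spectral norm differs
by at most √L and the cutoff is an order-of-magnitude device, so the
choice is reported in the output metadata).  The default cutoff is 1.0:
at or above it, a warning recommends the full scheme.  The flag fires at
`norm >= cutoff`.

The rotation MPO for one orbital is built as a four-state machine
(idle / open ↑-string / open ↓-string / finished), giving op-bond
dimension exactly b = 4 for any L; an MPO application multiplies bond
dimensions by at most b, and compression back to the configured m follows
every orbital (both modes) plus once between the two generator
applications of the full scheme.  The compression cadence changes
constant factors only, never the exact-m result.  The default m is the
input state's maximum bond dimension — the economical
compress-to-original-m choice; any larger value may be configured.

## Compression and its monitors

`compress` left-canonicalizes by a QR sweep, then truncates right-to-left
with SVDs, so the discarded weight — the sum of discarded squared
singular values over all bonds, reported on the scale of the state's true
squared norm — is well defined and equals the loss of squared norm.  The
output is **not** renormalized: overlap magnitudes are the quantity of
interest and silently restoring the norm would bias them.  Singular
values below 1e−14 relative are always dropped (exact Schmidt rank), so
product states factor to bond dimension 1 and dense→MPS→dense round
trips are exact to machine precision.

Two accuracy monitors accompany every transformation: the total discarded
weight, and ⟨Ŝ²⟩ before vs after.  The counter-rotation is built from
spin-summed excitations and therefore commutes with total spin: for a
spin-pure input the transformed state is still an Ŝ² eigenstate, so any
drift in ⟨Ŝ²⟩ is attributable to truncation.  The monitor is only
meaningful for spin eigenstates; on spin-mixed inputs the plain-
contraction expectation changes under the (non-unitary) transformation
even without truncation.

## State interaction

Overlaps after counter-rotation are plain coefficient contractions.
Transition one-particle densities are D_pq = ⟨A|E_pq|B⟩ (spin-summed) or
the four spin-resolved blocks.  SOC matrices contract the spin-resolved
densities with one-electron spin–orbit integrals in the Pauli form
H_SO = Σ_pq Σ_κ h^κ_pq · ½ Σ_στ σ^κ_στ a†_pσ a_qτ; integrals are
Hermitian and purely imaginary (hence zero-diagonal), accepted in hartree
or cm⁻¹ with an explicit unit tag; all output energies are in hartree
with a cm⁻¹ convenience column.  Integrals are declared over the active
orbitals of the orthonormal reference in which the coefficient matrices
are expressed; for a bra/ket pairing (A, B) the integral block used is
W_braᵀ h W_ket with W the active blocks of C_X·C^XA and C_Y·C^YB —
exact under the same no-mixing assumption the method already makes.

Missing multiplet components are generated by the total spin-lowering
MPO; S⁻|S, M⟩ = √(S(S+1) − M(M−1)) |S, M−1⟩ fixes Condon–Shortley
phases, and each lowered state is divided by that factor rather than
renormalized blindly (asserted against the dense ladder).

The spin-free Hamiltonian is taken **diagonal** in the supplied per-state
energies: off-diagonal spin-free elements between states of different
orbital bases would require two-electron transition densities, and
following common state-interaction practice for separately optimized
multiplets they are set to zero (declared in the report).  On a
nonorthogonal state basis the diagonal-energy operator is symmetrized as
½(diag(E)·S + S·diag(E)) before the generalized Hermitian eigensolve;
alternative orthogonalization conventions differ at second order in
S − I and are out of scope.  The solve itself is `scipy.linalg.eigh`
with the overlap as metric; positive definiteness and Hermiticity are
checked first.

## Synthetic generators — what they emulate, and what they do not

* `random_orbital_pair` produces C_X = I and C_Y = exp(θK) for a seeded
  antisymmetric K normalized to unit Frobenius norm, block diagonal over
  the inactive/active split, with S_AO = I.  θ therefore directly
  controls the orbital dissimilarity, standing in for a geometry
  displacement or a change of spin manifold.
* `toy_hamiltonian_states` diagonalizes a nearest-neighbor Hubbard chain
  (defaults t_hop = 1, U = 4 — the smallest standard model with
  nontrivial multireference singlet/triplet manifolds) in an (N, S_z)
  sector, disentangles degenerate multiplets by subspace diagonalization
  of Ŝ², and fixes phases by making the first sizable amplitude real
  positive.  Eigen-residuals are checked below 1e−10.
* `make_soc_integrals` draws h^κ = i·scale·(A_κ − A_κᵀ); the default
  demo scale of 1e−4 hartree (~20 cm⁻¹) is representative of
  singlet–triplet couplings in heavy-element complexes.
* `build_scan` traces the accuracy of both schemes against the dense
  oracle along an ascending θ grid with fixed states and generator —
  the synthetic analogue of a rigid bond stretch.  The default
  ten-point grid θ = 0.1 … 1.3 makes the deviation norms span the
  cutoff of 1 from both sides, which is the point of the experiment.

These generators exercise every code path at machine precision, but they
do not reproduce real DMRG-SCF features: truncated (m-limited) input
states, near-singular orbital overlaps from drastically different
geometries, inactive–active mixing, or realistic integral magnitudes and
sparsity.  Passing tests demonstrate the exactness and scaling properties
of the transformation algorithm itself, not chemical accuracy for any
molecule.

## Numerical choices and degenerate inputs

* Unpivoted Doolittle LU with pivot tolerance 1e−12; singular S^XY is
  rejected before inversion via an SVD conditioning guard.
* `mps_from_dense` rejects zero vectors (no meaningful Schmidt
  decomposition); `scale(psi, 0)` produces an explicit zero state.
* Dense expansion (`mps_to_dense`) is capped at L = 10 by default.
* Orbital indices are 0-based internally; every file format and report is
  1-based, converted at the I/O boundary only.
* The dense oracle is deliberately simple (O(16^L) overlaps, factorized
  per spin channel within each sector); the L ≤ 6 test cap keeps it
  fast.  The occupation-string ↔ (↑ block, ↓ block) determinant phase is
  the most bug-prone convention in the package and has an exhaustive
  L = 3 test.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the oracle-equivalence grid
at L = 2…6 with ten seeded rotations per size (50 total) and electron
counts cycling through each size's sectors; scans use L = 4, four
electrons, three states; SOC experiments use L = 3 with two singlets and
two triplets (eight multiplet components).  These sizes make every
comparison against the exponential-cost dense oracle exact and keep the
complete suite in the tens of seconds on one CPU.

## Known limitations

* No DMRG sweep optimizer: states enter as dense vectors (or MPSs from
  file); the package transforms and couples states, it does not optimize
  them.
* No two-electron spin–orbit terms, no mean-field (AMFI-type) integral
  construction, no spin-free cross-basis off-diagonals, no g-factors.
* No automatic mode switching mid-run and no bond-re-expansion
  techniques; the linearized scheme is chosen (or warned about) per run.
* No non-Abelian spin adaptation of the MPS.
* No readers for program-specific orbital/wave-function formats.
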