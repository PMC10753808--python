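# Methods

## The problem

The two-particle reduced density matrix (2-RDM) of an electronic system,
`P_ik,jl = <a†_i a†_k a_l a_j>`, determines the energy of any two-body
Hamiltonian through

    E = sum_ij t_ij D_ij + 1/2 sum_ikjl V_ikjl P_ik,jl + E_core,

with the 1-RDM `D` obtained by contraction, `sum_k P_ik,jk = (N_el - 1) D_ij`.
Obtaining every element of `P` is expensive — deterministically (each element
is a separate calculation) or statistically (each element carries shot noise
on a quantum device).  This package reconstructs `P` to chemical accuracy
from *partial* information: a subset of elements, possibly noisy, completed
under a low-rank assumption, with every free parameter of the completion
chosen from a cheap *model* 2-RDM rather than from the expensive target.

## Representation

With real orbitals and a good `Sz`, only three spin sectors are unique and
nonzero: aaaa, bbbb and abab.  Same-spin sectors have an 8-fold
permutational symmetry and are stored as symmetric matrices over strictly
ordered orbital pairs `i > k` (dimension `n(n-1)/2`; the diagonal pairs
vanish identically by antisymmetry); abab has only the 2-fold pair-exchange
symmetry and is stored over all `n^2` ordered pairs.  Packing is 0-based
lexicographic, `a = i(i-1)/2 + k`, and unpacking restores all symmetry
orbits with the sign rule (odd transpositions flip the sign).

A mean-field (idempotent-`D`) 2-RDM has sector ranks `Ns(Ns-1)/2` and
`Na*Nb` — the minimum ranks of an electronic system.  Correlation adds
singular values that decay approximately exponentially, which is what makes
low-rank completion viable at a rank only slightly above the mean-field one.
A state with fewer than two electrons in a spin channel has that same-spin
sector identically zero; the often-quoted count of "three unique nonzero
sectors" therefore applies only when both channels host at least one pair
(a two-electron active space has a single, exactly rank-one abab sector —
the outer product of the pair amplitude with itself).

## Completion

A sector is recovered from sampled unique elements `Omega` by minimizing
`sum_{(ij) in Omega} [(L^T L)_ij - M_ij]^2` over a real `r x d` factor `L`
(L-BFGS-B, iteration cap 15 000), so every iterate is symmetric PSD.
Numerical choices:

* **Initialization.** Truncated eigendecomposition of the zero-filled
  observed matrix plus seeded Gaussian noise of relative scale `1e-2`.
* **Tolerances.** Gradient tolerance `1e-10`; a second optimizer pass from
  the first pass's endpoint ("polish") clears the quasi-Newton memory and
  routinely gains one to two digits near the objective's numerical floor.
* **Divergence guard.** The factorized objective admits spurious minima in
  which the factor norm explodes while still fitting `Omega` (typically
  when a sampling pattern leaves a row under-constrained).  A run whose
  squared factor norm exceeds `max(10, 3 sqrt(d))` times the full-matrix
  Frobenius norm extrapolated from the observed entries is abandoned
  mid-optimization and retried from a fresh start (up to 3 times); if every
  start diverges the result is returned flagged `converged=False`, and all
  averaged quantities exclude unconverged trials.
* **Restarts.** One warm start by default; ties among restarts are broken
  by the lowest final objective.
* **Trial validity screens (noiseless driver).** Averaged results exclude
  a sampling trial when any of three observable conditions fails: an
  optimizer run did not converge; the sampling's off-diagonal observation
  graph is disconnected over the matrix rows (the completion is then not
  identifiable — distinct completions fit `Omega` with identical
  objectives, differing by relative signs or mixings between graph
  components); or the paired *model* completion on the same `Omega`
  misses `eps0` (the model is fully known, so this is measurable in
  practice, and it marks the sampling as belonging to the failure tail
  the 90% calibration criterion tolerates — using it would also corrupt
  the model-residual correction).  At production matrix sizes uniform
  sampling above the information bound is connected with overwhelming
  probability and these screens are inert; at desk-scale dimensions they
  fire on occasional draws and keep the 10-trial averages meaningful.

The error metric is the relative Frobenius error
`eps = ||M_est - M||_F / ||M||_F`; across sectors, errors aggregate as the
norm-weighted (block-diagonal) combination.  The information bound
`(2rd - r^2 + r) / (d(d+1))` is the fraction of unique elements below which
a rank-`r` symmetric matrix is underdetermined; completion degrades sharply
near it and saturates at the rank-truncation error well above it.

## Model-steered parameter selection

* **Rank** (per sector): smallest `r` with relative truncation error of the
  *model* spectrum at most `kappa * eps0`, with `kappa = 1/2` and
  `eps0 = 1%` by default, reserving half the error budget for completion.
* **Coherence.** Uniform element sampling is efficient only if the top-`r`
  subspace `U` is incoherent, `mu = (d/r) max_i ||row_i(U)||^2` near 1.
  Canonical molecular orbitals are nearly maximally coherent, so an
  orthogonal orbital rotation `C` is optimized on the model to minimize a
  smooth surrogate of `mu`: the power-mean `sum_i ||row_i(U)||^(2p)` with
  `p = 8`, over `C = C0 exp(A)` with skew-symmetric `A`, from the identity
  plus 10 Haar-random starts (the start with the lowest surrogate wins;
  failed starts are discarded).  One rotation serves all sectors jointly
  with equal weights, since a single measurement basis must serve the whole
  2-RDM.  By default the rotation is spin-restricted (one spatial `C` for
  both channels): this keeps the co-rotated integrals spin-free, so energy
  checks remain exact; the unrestricted variant is available for rotating
  RDMs alone.  Orbital rotation is not an orthogonal map on packed
  same-spin representatives, so sector singular values are not exactly
  invariant — only traces and (with co-rotated integrals) energies are, and
  only those are asserted.
* **Sampling fraction, noiseless:** smallest `f` on a 12-point geometric
  grid from half the information bound to 1 at which the model completes to
  `eps <= eps0` in at least 9 of 10 independent random samplings.  With 10
  trials this is a binomial estimate; at desk-scale ranks (`r ~ 2`) the
  success-versus-`f` transition is smeared by per-row coverage fluctuations
  (about `4r` samples per row at twice the bound), so a calibrated fraction
  can sit on the transition shoulder.  Larger selected ranks sharpen it.
* **Counting convention.** `f_sample` counts unique *packed matrix
  elements* per sector (lower triangle), in both the noiseless and noisy
  settings; this is also the denominator of the information bound.  The
  measurement layer independently groups sampled elements into fermionic
  quartets (three permutationally related elements share one quartet's 8
  strings), so quartet-based accounting is always available from a
  measurement plan, but fractions are never quoted in quartet units.
* **Shots and fraction, noisy:** ascending a shot grid (powers of
  `sqrt(10)`), each shot count is scanned over the `f` grid (10 samplings
  each, unconverged completions excluded) for its best mean model error;
  the smallest shot count reaching `eps0` wins.  The baseline `m0` is the
  standard scheme — every required Pauli string measured with equal shots,
  no completion — bisected on the same grid against `eps0` on the same
  model; the cost ratio is `f_m = m / m0`.  In practice the optimal
  fraction is at or near 1: completion earns its keep as a low-rank *noise
  filter*, not by skipping elements.

## Measurement simulation

Fermions map to qubits by the Jordan-Wigner encoding in blocked spin-orbital
order (all alpha orbitals ascending, then all beta).  For a quartet of four
distinct labels, the three permutationally unique two-body expectations are
linear combinations of the same 8 Pauli strings (X/Y on the four sites, even
Y parity, Z fill between site pairs); quartets with repeated labels reduce
to smaller Z-containing sets, down to `<n_i n_k> = (1 - <Z_i> - <Z_k> +
<Z_i Z_k>)/4`.  All tables are derived symbolically from the ladder-operator
expansion at run time — nothing is hard-coded — and validated in the test
suite against an independent dense-statevector oracle.

True string expectations are computed directly from the stored RDMs by
inverting the encoding: each string is recognized as a product of Majorana
operators times standalone `Z` factors, expanded into ladder monomials,
normal-ordered, and evaluated against the 1-/2-RDM (real wavefunctions are
assumed; odd-Y strings have zero expectation and are never measured).
Measuring a string with `m` shots draws the +1 count from a binomial
distribution — an unbiased estimate of `<Q>` with variance
`(1 + <Q>)(1 - <Q>)/m`.  Strings shared between quartets are measured once
and reused; the reported average shots per unique element,
`m_bar = m * n_strings / n_unique_elements`, follows this convention.  The
optional switch-cost model prices each distinct measurement setting at `c`
shots: `cost = sum_Q m_Q + c * n_settings`.

## Postprocessing

Noiseless completion: (1) sampled entries are restored to their exact
values, (2) each sector's packed trace is rescaled to its electron-count
target (`Ns(Ns-1)/2`, `Na*Nb`), (3) the model's own completion residual —
the model minus its completed-and-postprocessed self, same samplings and
ranks — is added.  Step 3's processed-model convention makes the correction
exact in the limit where the target coincides with the model.  Noisy
completion applies only step 2: the sampled values carry noise and the
model correction would reimport it.  Rank truncation systematically lowers
the trace, and the trace enters the energy linearly, so normalization is
the step that removes the bulk of a truncation-dominated energy error.

## The toy electronic-structure engine

No external quantum-chemistry backend is required.  Toy molecules are
seeded model Hamiltonians: a diagonally dominant one-electron matrix with
levels from -3.0 to -0.3 Hartree, plus a two-electron kernel that is the sum
of a Coulomb-like diagonal term (`0.4/(1+|i-k|)` Hartree) and a random PSD
supermatrix (scale 0.15) projected onto the 8-fold-symmetric subspace.
These scales were chosen once to emulate weakly correlated small molecules:
correlation energies of 5-30 mHa, ground states dominated by the aufbau
determinant (weight > 0.97; the builder refuses fixtures below 0.6), and a
model-target 2-RDM mismatch of 1-2%, matching the regime in which a cheap
perturbative density matrix is a sensible guide for a coupled-cluster-grade
target.  The pipeline per preset: unrestricted Hartree-Fock in the toy
basis; transform to the (alpha) canonical molecular-orbital basis — a
single spatial basis keeps the active integrals spin-free; fold any frozen
core into the active integrals and core energy; exact diagonalization in
the particle-number sector for the *target* 2-RDM; and a first-order
perturbative wavefunction with Epstein-Nesbet denominators for the *model*
2-RDM.  The internal energy identity (RDM-contracted energy equals the
eigensolver energy to 1e-9) cross-validates every convention in the chain.

What these fixtures do **not** emulate: basis-set effects, point-group
symmetry, size extensivity across molecules, relaxation contributions to
the model density matrix, and strong multireference correlation.  Passing
tests demonstrate the protocol's correctness and its behavior in the
weakly correlated low-rank regime, not production-scale cost reductions.

Synthetic PSD fixtures complement the toys: `M = U L U^T` with a `1/(1+i)`
head over the requested rank, an exponential tail of prescribed log-slope
(the spectral shape of correlated 2-RDM sectors beyond their mean-field
rank), and eigenvectors interpolated between Haar-random and
axis-aligned by a Givens-mixing knob.  At knob 0 the coherence statistics
match directly sampled Haar subspaces (for small ranks this is noticeably
above 1 — the maximum of `d` leverage scores concentrates near
`chi^2_r / r` extremes, about 2.7 at `d = 50, r = 5` — so tests compare
against the sampled Haar reference, not against 1).

## Problem sizes and defaults

The shipped experiments run on active spaces of 3-6 spatial orbitals
(sector dimensions up to 36, Fock spaces up to 4096), 10 samplings per
calibration point, 12-point sampling grids and shot grids of powers of
`sqrt(10)` from 1e3 to 1e8 — sizes chosen so a full noiseless protocol
completes in seconds and a full noisy protocol in about a minute on one
core.  Trend tests (shot-count monotonicity, cost reduction versus relative
rank) use trimmed grids and 4 samplings; the headline runs use the full
defaults above.

## Known limitations

* No N-representability enforcement: completed sectors are PSD by
  construction but not guaranteed to correspond to a physical state.
* Pauli strings are measured independently; grouping of commuting strings
  and classical-shadow estimators are out of scope.
* The noisy pipeline assumes pure shot noise (binomial); no device error
  model.
* `k`-RDMs with `k > 2` are not represented.
* Desk-scale fixtures make some of the production-scale phenomenology
  marginal:
  with small ranks the calibration transition is smeared (see above), and
  trace-normalization's error reduction is modest when the truncated tail
  carries little trace.
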