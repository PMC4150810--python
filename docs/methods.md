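# Methods

## Problem and observable

Single-molecule experiments show that transcription factors (TFs) whose
binding site lies in the entry–exit region of a nucleosome dissociate two to
three orders of magnitude faster than from naked DNA. `nucoff` implements
two candidate mechanisms as continuous-time Markov chain (CTMC) models and
asks which can quantitatively produce such an acceleration without any
direct nucleosome–TF force:

1. **Dimeric binding** (`nucoff.dimeric`): a homodimeric TF (LexA-like)
   releases one half-site at a time; the nucleosome rewraps onto the
   released half-site and blocks rebinding, ratcheting the TF off.
2. **Non-specific binding** (`nucoff.nonspecific`): the TF slides base by
   base between its specific site and non-specific DNA; the nucleosome
   rewraps behind it and blocks the return to the site.

Every model is a generator matrix `R` acting on state concentrations,
`dX/dt = R X`, with column convention: entry `(j, i)` is the rate from
state `i` to state `j`, diagonal entries close each column to zero.  The
experimentally detected "off" state (TF free *and* nucleosome fully
wrapped, the high-FRET state) is made absorbing by zeroing the single rate
out of it (`k4` on naked DNA, `k8` on the nucleosome) — never by deleting
rows or columns, so the printed matrix shapes are preserved.  The measured
off-rate is the magnitude of the nonzero eigenvalue of smallest magnitude,
i.e. the slowest exponential decay toward that steady state
(`nucoff.markov.slowest_decay_rate`).

Energies are in units of kBT throughout (kBT ≡ 1); rates in 1/s,
concentrations in nM, DNA lengths in bp.

## Dimeric model

Naked DNA has four states (dimer fully bound; either single half-site
bound; unbound) and four rates: `k1` half-site rebinding, `k2` release of
one half-site from the dimer, `k3` release of the last half-site, `k4`
association per half-site per nM.  With `k4 = 0` the slowest decay has the
closed form

    k_off = 1/2 [ (k1 + 2 k2 + k3) − sqrt((k1 + 2 k2 + k3)² − 8 k2 k3) ].

Three measured constraints close the system: the overall naked off-rate
(0.0034 1/s), the ~1000-fold half-site affinity penalty (`k1/k2 = 1000`,
from the Boltzmann relation between the partial- and full-binding free
energies), and the monomer-symmetry assumption `k2 = k3`.  The fit solves
the closed form for `k = k2` by bracketing root-search on `k ∈ [1e-8, 1e8]`
1/s (the closed form is homogeneous of degree one, hence strictly monotone
in `k` at fixed ratio), giving `k1 ≈ 1705`, `k2 = k3 ≈ 1.705` 1/s.
`k4 = k2 k3 / (k1 Kd)` with the overall `Kd = 0.07` nM reproduces the
four-state equilibrium occupancy and evaluates to ≈ 0.0244 1/(s nM).

Next to a nucleosome the same TF rates combine with coarse-grained
wrap/unwrap rates between three unwrapping extents — fully wrapped
(`n_wrap = 0`), half-site exposing (`n_part`), full-site exposing
(`n_full`) — into the seven-state model.  Lumping `m` sequential single-bp
steps into one transition divides the base rate: `k5 = k0/(n_full −
n_part)` (rewrap past the inner half-site), `k7 = k0/(n_part − n_wrap)`,
with reverse rates carrying the Boltzmann factors `k6 = k5 e^(−ddG)`,
`k8 = k7 e^(−[dG(n_part) − dG(n_wrap)])`.  Here `ddG = dG(n_full) −
dG(n_part)` is the one parameter the off-rate is sensitive to; the spans
enter only through `k5`, `k7` and matter little (doubling `n_full − n_part`
shifts the off-rate by ~5%, versus ~50% for a 1 kBT change in `ddG` — a
tested property).  Defaults `n_full = 34`, `n_part = 19` are one consistent
choice for a 20-bp site at positions 8–27 plus clearance; the exact values
are unknown and immaterial.  `k0 = 1e5` 1/s is the base rate of single-bp
wrapping fluctuations.

The default scan covers `ddG = 5..7` kBT in 0.25 steps (the range
consistent with plausible unwrapping extents on a strong positioning
sequence); at zero concentration it yields off-rates 0.195–0.632 1/s, a
57–186-fold acceleration.

**Mutant predictions.** With one half-site mutated away the seven states
reduce to three: TF bound to the intact half (at the extent exposing it),
TF free at that extent, and the rewrapped absorbing off state; the rewrap
step past the site is `k7` (distal half intact) or `k5` (proximal half
intact).  At zero concentration the slowest decay is `k3` exactly in the
relevant regime (`rewrap ≫ k3`) — a 500-fold acceleration that is
*independent* of `ddG`, which distinguishes the mechanism experimentally.

**Entry–exit sites.** For a site straddling the positioning-sequence
boundary (outer half always bindable, inner half exposed after `n_in` bp of
unwrapping) the model tracks the wrap coordinate base by base on a full
landscape while the TF holds only the outer half or is free; rewrapping
below `n_in` is blocked while the inner half is occupied.  The wrap
coordinate is pinned at `n_in` while the inner half is bound (further
transient unwrapping above `n_in` has negligible occupancy and no kinetic
role at the reported precision).  The result depends on the landscape
between 0 and `n_in`, not on a single free-energy difference, so no
literature value is asserted for it.

## Landscape

`FreeEnergyLandscape` stores `dG(n)` for `n = 0..n_max` bp unwrapped,
anchored at `dG(0) = 0`.  Single-bp kinetics follow local detailed balance:
rewrap at `k0`, unwrap at `k0 e^(−[dG(n) − dG(n−1)])`.  The published
landscape of the 601 positioning sequence is not redistributable here, so
`synthetic_landscape` provides deterministic stand-ins: linear ramps with a
realistic overall cost of 30–40 kBT over 147 bp (default 35), optionally
with a Gaussian dyad barrier.  Consequently:

* results that depend only on `ddG` (the whole dimeric analysis) are
  faithful as stated;
* results tied to the *shape* of the real 601 landscape — the optimal
  clearance `d = 7`, the shifted-site fold changes, the ~1.45 1/s
  entry–exit rate — are implemented as procedures and reported, not
  asserted against literature values.  Passing tests on the synthetic
  family show the mechanism-level conclusions are landscape-robust within
  30–40 kBT linear ramps, not that any specific number transfers to the
  601 sequence.

## Non-specific (sliding) model

The TF occupies a 20-bp footprint (site length) whose position `p` is its
entry-side edge on a 1D lattice; it slides ±1 bp at `k1` from non-specific
positions and at `k2 = k1/K` off the specific position, and dissociates at
`kns_off = K·ks_off` (non-specific) or `ks_off` (specific), with
`K = Kd(ns)/Kd(s)` the specificity ratio.  Association is position-uniform
at `ks_off/Kd(s)` per nM.  Ends are reflecting.  For each `(K, k1)` the one
free parameter `ks_off` is fitted so the naked lattice decays at 0.0034 1/s.

**Lattice geometry.** The default lattice is the bare 147-bp positioning
sequence (`L = n_max = 147`, site at 8–27).  Free flanking DNA is
supported (`L > n_max`) but deliberately not the default: flank positions
cost no unwrapping free energy, so for large `K` the bound ensemble drains
into the flank where dissociation is `K`-fold faster, and the slow mode
saturates near `kns_off` — fold changes of order `(K + n_ns)/n_ns`
(hundreds at `K = 1e5`).  That reservoir physics is real for long naked
overhangs but is not the nucleosome-competition question the model poses;
with the bare lattice the specific site (Boltzmann weight `K e^(−dG)`)
dominates the bound ensemble for all grid values of `K`, and the scan
reproduces the model's central negative result.

**Joint model.** States are pairs `(p, n)` plus `(free, n)`.  A TF at `p`
requires `p + footprint − 1 + d ≤ flank + n` (the clearance `d` is the
minimum distance between the TF's wrap-proximal edge and the wrap
boundary); rewrapping or sliding that would violate the clearance is
blocked.  The wrap coordinate moves with the single-bp landscape rates in
every state; `(free, 0)` is the absorbing off state.  The scan maximizes
the off-rate over `d = 0..21` (ties take the smallest `d`) and over
concentration (0–50 000 nM; the maximum sits at 0, where re-association
cannot recapture the TF), as an upper bound on the mechanism.  The `(K,
k1)` grid is 7 log-spaced `K` in 1e2..1e5 × 5 decade `k1` in 1e3..1e7 = 35
conditions.  On the synthetic 30/35/40-kBT linear landscapes the maximal
fold change across the entire grid stays below 10 (mostly below ~1):
sliding cannot produce the observed acceleration.

## Numerics

* **Eigenvalue extraction.** Dense `eig` for dense generators.  Sparse
  generators: structurally absorbing states (all-zero columns) are removed
  — each contributes exactly one zero eigenvalue — and the transient block
  is solved by shift-invert Arnoldi around 0 (`k = 2`, fixed all-ones start
  vector for run-to-run determinism).  When the block is narrowly banded
  (the `(n, p)`-interleaved state ordering gives bandwidth ≈ one block
  size, two orders of magnitude below the matrix size) the inversion uses a
  LAPACK banded LU (`dgbtrf`/`dgbtrs`); otherwise SuperLU.
* **Zero classification.** Dense path: an eigenvalue is "zero" below
  `1e-10 × max|diag|`, a scale-free cutoff across rate magnitudes spanning
  1e-3–1e7 1/s.  Sparse path: after structural absorbing removal a zero can
  only mean disconnection from absorption, while genuine decays may lie
  10+ orders below the fastest rates, so the cutoff is the machine floor
  (`100 ε max|diag|`); exact singularity is also caught at factorization.
* **Naked-lattice fit.** The bound block is tridiagonal and reversible; it
  is symmetrized by the geometric-mean transform and solved with
  `eigh_tridiagonal`, then polished by shifted inverse iteration in
  extended precision.  A plain dense eigensolve is accurate only to
  ~`ε‖Q‖`, which at `k1 = 1e7` 1/s swamps a 3.4e-3 1/s decay; the polished
  solve round-trips the fit to ~1e-7 relative over the whole grid.
* **Wrap-state truncation.** Joint-model wrap states whose suffix-minimum
  free energy exceeds the site-exposing free energy by more than 8 kBT are
  dropped; the suffix-minimum rule never cuts off a well hidden behind a
  barrier, and the induced eigenvalue error is bounded by ~`e^(−8)` ≈ 3e-4
  relative (measured ≈ 2e-4 on the default geometry).  Truncation is
  disabled automatically for flat landscapes and in all small-instance
  oracle comparisons.
* **Gillespie oracle.** Exact SSA (numba-compiled jump loop, dense jump
  tables, ≤ 5000 states) from a fixed seed.  The decay rate is estimated by
  log-linear least squares on the empirical survival function beyond its
  median — the regime where only the slowest mode survives — excluding
  points with fewer than 8 surviving trajectories (the log of the extreme
  empirical tail is biased downward; without trimming the 4-state fixture
  shows ~5% bias).  The standard error is `rate/sqrt(m)` for `m` tail
  points, and eigenvalue agreement is asserted within 3 SE.
* **SSA feasibility.** Cross-checks against the eigensolve run on small
  instances (toy 16-bp lattices, reduced `k0`) and on grid points with
  `k1 ≤ 1e5` 1/s: an exact simulation at `k1 = 1e7` with a ~1e-3 1/s decay
  would take ~1e9–1e10 jump events per estimate.  The eigenvalue method has
  no such limitation; this only bounds where the stochastic cross-check is
  run.
* **Problem sizes in the test suite.** Small-instance oracles use `L ≤ 25`,
  `n_max ≤ 30` (dense enumeration); the negative-result scan runs the full
  35 × 22 × 4 condition grid on the three-landscape family at the default
  truncation margin.

## Degenerate inputs and tie-breaks

`k1 = 0` decouples lattice positions (decay = the start position's
dissociation rate); `K = 1` removes specificity; `total_dG ≤ 0` landscapes
are rejected (a flat landscape is approximated by a small positive total);
scan ties in `d` resolve to the smallest `d`, then the smallest
concentration.  Generators with no nonzero eigenvalue raise (`NoDecayError`)
rather than returning 0; multi-dimensional null spaces raise with the zero
count.

## Limitations

* No direct steric or electrostatic nucleosome–TF forces: both models
  deliberately quantify how far pure binding-equilibrium shifts go; the
  remaining ~5–10× gap to the measured 1000-fold acceleration is outside
  their scope.
* Single TF, single nucleosome; no 3D hopping between distant sites, no
  neighboring-nucleosome effects, no time-dependent rates.
* The Gal4 system is not parameterized (its monomer affinity is not
  available); the machinery accepts arbitrary `ratio`/`Kd` so users can
  model dimeric TFs other than LexA.
* Synthetic landscapes emulate only the overall scale (30–40 kBT) and
  optionally a dyad barrier, not the bp-resolved ruggedness of a real
  positioning sequence; landscape-shape-specific numbers should be
  recomputed with a measured landscape via `load_landscape`.
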