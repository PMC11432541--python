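# Methods

## The model

`sbsfold` implements the strings-and-binders (SBS) picture of chromatin
folding: a chromosomal segment is a coarse-grained bead-spring polymer whose
beads carry binding-site labels, immersed in a bath of diffusing spherical
binders.  A binder of type *k* attracts only beads whose label set contains
*k*; by bridging two or more cognate sites a binder creates an effective
bead-bead attraction, and above characteristic thresholds in binder
concentration *c* (volume fraction) and affinity *E*<sub>bb</sub> (k<sub>B</sub>T)
the chain switches from a self-avoiding coil to a phase-separated globule.
Overlapping, combinatorial binding domains (beads holding several labels)
produce micro-phase-separated multi-globule structures and a degenerate
folding landscape — the source of the single-molecule heterogeneity the
analysis suite quantifies.

Assumptions inherited from the coarse-grained framework: implicit solvent
with over-damped-ish Langevin dynamics (no hydrodynamics), all beads and
binders of equal diameter σ = 1 and mass m = 1, k<sub>B</sub>T = 1, no
binder-binder attraction, and chain connectivity that cannot be cut
(topological effects from bond crossing are not analysed).

## Potentials and conventions

* **FENE bonds** between consecutive beads:
  U = −½KR₀² ln(1 − (r/R₀)²) with R₀ = 1.6 σ and K = 30 k_BT/σ²;
  diverges at R₀, so the bound r < R₀ is checked every step.
* **Excluded volume**: WCA potential (Lennard-Jones truncated at 2^(1/6) σ
  and shifted to zero there) between all non-cognate pairs, including
  bonded beads; FENE + WCA puts the equilibrium bond near 0.97 σ.
* **Cognate attraction**: a bead-binder pair with matching label interacts
  through a single full Lennard-Jones potential of depth ε = E_bb,
  truncated at 1.5 σ and shifted to zero at the cutoff, *replacing* the WCA
  term for that pair (the standard choice in LAMMPS-style SBS work).  Note
  that energy-shifting the 1.5 σ truncation reduces the escape barrier
  from the minimum to ≈ 0.68 ε; codes that truncate without shifting
  effectively use a deeper well, so affinity thresholds quoted here are
  ≈ 1.5× larger than in unshifted implementations.
* **Periodic boundaries**: cubic box, minimum image.  Bead positions are
  integrated unwrapped (the chain stays spatially contiguous, which is what
  the distance/shape analysis needs); a wrapped copy of all coordinates is
  maintained for the neighbour search, where minimum image reduces to a
  single ±L correction.

## Integration and thermostat

Velocity-Verlet with timestep Δt = 0.012 (model time; standard for
Kremer-Grest-type chains — the underlying study does not state its step).
The Langevin thermostat enters the force evaluation between the two
half-kicks as −ζ m v plus noise of per-component variance 2ζmk_BT/Δt with
ζ = 0.5.  The noise is **uniform** with exactly matched variance
(Dünweg-Paul form, as in LAMMPS `fix langevin`): over the ≈ 1/(ζΔt) ≈ 170
kicks per velocity relaxation time the accumulated impulse is Gaussian to
high accuracy, and the stationary temperature is exact by construction.
The kinetic temperature test recovers ⟨v²⟩ = T within ~1.5% at these
parameters (finite-Δt bias), inside the 3% tolerance asserted.

Neighbour search: two Verlet lists (non-cognate pairs within
2^(1/6) σ + skin, cognate pairs within 1.5 σ + skin, skin = 0.3 σ) built
from a counting-sort cell grid and rebuilt whenever any particle has moved
more than skin/2 since the last build — the conservative criterion that
guarantees no interacting pair is ever missed.  The contract, enforced by
test, is exact agreement with a direct all-pairs evaluation.  All
stochastic streams derive from `numpy.random.SeedSequence` fan-out (per
stage, per replicate, per chunk), so every run is reproducible from one
master seed; the kernel-internal uniform stream is an explicit
xorshift128+ seeded per chunk.

## Initial states

Initial conformations are self-avoiding walks with unit bonds grown
*confined inside the box* (0.5 σ wall margin) and then equilibrated with
pivot moves, which restore the true SAW measure (sequential growth alone
is a kinetic-growth walk with a visibly smaller Flory exponent; the pivot
chain reproduces ν ≈ 0.59 within the tested tolerance when unconfined).
Confinement matters: a free-space coil longer than the box winds around
the periodic torus, and a wound chain's unwrapped gyration radius can
never collapse.  Binders are injected uniformly, rejecting positions
closer than 1.0 σ (minimum image) to any particle — at exactly 1 σ both
WCA and cognate LJ are zero, so the initial state carries no potential
energy spikes.

## Collapse detection and phase diagram

The gyration radius of the beads is recorded at every sampling interval.
The coil level is the mean of the first 5% of samples, the plateau the
mean of the last 25%; a track whose relative drop is below 10% reports no
collapse, otherwise the collapse step is the first sample at which the
moving-average-smoothed track (window ≈ n/25 samples) falls below the
coil/plateau midpoint.

Sweeps run replicate simulations over a (c, E_bb) grid with independent
derived seeds.  The threshold estimator first projects the noisy plateau-Rg
response onto a non-increasing curve by isotonic regression — which
guarantees a single midpoint crossing — and then interpolates linearly
(in log-parameter space for concentration grids, so a sharp step lands on
the geometric mean of the bracketing points).

## Ensemble and single-molecule analysis

* **Contact maps**: A_ij = 1 iff |r_i − r_j| < θ (strict), θ default 3.5 σ
  (≈ 258 nm; the supported 2-5 σ range maps to ≈ 150-350 nm).  Diagonal
  fixed at 1 and excluded from every statistic.  Ensemble maps are
  entrywise means; block binning (e.g. factor 10: 800 beads of 2.5 kb →
  80 bins of 25 kb) matches experimental resolutions.
* **Comparison statistics**: Pearson r, Spearman r_s (mean ranks on ties)
  and the genomic-distance-corrected r′, all over upper-triangle
  off-diagonal entries with masked (NaN) bins dropped pairwise.  r′
  residualises *each matrix by its own* per-|i−j| mean before correlating;
  a matrix that depends only on |i−j| residualises to zero and is flagged
  degenerate rather than silently returned as 0.
* **Heterogeneity**: the same r′ applied to single-molecule Euclidean
  distance matrices, over all unordered pairs of molecules; unimodal with
  a small positive mean for a phase-separated SBS ensemble (structural
  correlation through the shared binding profile), ≈ 0 for independent
  random coils.  Short chains (≲ 50 beads) carry a small positive
  end-effect bias even for independent coils.
* **Shapes**: the inertia tensor about the centre of mass is diagonalised;
  with moments I_a ≤ I_b ≤ I_c the equivalent uniform ellipsoid has
  a² = (5/2N)(I_b + I_c − I_a) (cyclic), pairing the smallest moment with
  the longest semi-axis so a/c ≥ 1 by construction.  Negative radicands
  (degenerate clouds) are clipped to zero and flagged, and degenerate
  molecules are excluded from ensemble summaries with a reported count.
  The gyration tensor gives λ₁ ≥ λ₂ ≥ λ₃, ellipticity ε = 2λ₃/(λ₁+λ₂)
  (1 for a sphere) and Rg² = tr T.  Volumes: V = (4/3)πabc and
  V = (4/3)πRg³, averaged per molecule (means of per-molecule volumes,
  not volumes of mean descriptors).
* **Mann-Whitney U**: U = Σ[x_i > y_j] + ½[x_i = y_j]; exact two-sided
  p for small samples (n·m ≤ 400) via the tie-free DP null distribution,
  full enumeration of group assignments for small tied samples, and the
  tie-corrected normal approximation with continuity correction otherwise.

## Unit calibration

σ maps to physical length two independent ways: genomic density
σ = (s/G)^(1/3)·D (s bp per bead, G genome size, D nucleus diameter) and
imaging σ = Rg_imaging/Rg_model; the reference value is their mean.  With
the human sub-megabase defaults (s = 2500 bp, G = 6 Gb, D = 10 μm,
Rg = 464 nm vs 6.4 σ) these give 74.7 nm, 72.5 nm and 73.6 nm.  Time maps
through Stokes drag, τ = 6πησ³/(k_BT), ≈ 18 ms at η = 0.01 Pa·s and
T = 300 K — tens-of-milliseconds dynamics per model time unit.

## Synthetic data: what it emulates and what it does not

The binding-profile generator tiles the chain with contiguous domains
(geometric length distribution), assigns types round-robin so every type
appears, overlaps consecutive domains so that the expected multi-label
fraction equals `overlap_prob` (a deficit-feedback correction keeps the
realised fraction on target despite rounding and triple coverage), and
clears an `inert_frac` subset.  This reproduces the *statistical* features
of an inferred chromatin binding landscape — overlapping combinatorial
domains, inert stretches, several binder types — but not any particular
locus: real inferred profiles have hierarchical, nested domain structure
tuned to an experimental contact map, which is exactly the input this
package treats as out of scope.  Toy contact maps (TAD blocks × power-law
decay, loop bumps, multiplicative noise) serve as ground-truth comparison
targets, and uniform ellipsoid clouds / rod / ideal-chain / SAW baselines
are the analytic oracles for the shape and correlation machinery.

Consequently, passing tests demonstrate that the machinery measures what
it claims on systems with known answers and that the SBS physics
(thresholded collapse, micro-phase separation, heterogeneity) emerges at
desk scale; they do not certify agreement with any experimental Hi-C or
microscopy dataset.

## Study conditions at desk scale

The reference "desk" experiment uses a 200-bead chain with 4 binding-site
types (10 domains, mean length 26 beads, 30% multi-label, 5% inert,
profile seed fixed as a study input), box 20 σ, total binder volume
fraction 0.05 split equally over types (≈ 3 binders per cognate bead) at
E_bb = 5 k_BT, 50 replicate collapses of 1.2×10⁵ steps (collapse completes
by ≈ 3-6×10⁴ steps; the final quarter is a clean plateau).  The
concentration sits inside the globular phase: scans showed collapse for
c ∈ [0.03, 0.1] at E = 5, a coil below, and — notably — *no* collapse at
c = 0.2 with four types, where ≈ 14 binders per cognate bead saturate
every binding site (coating/re-entrant regime, a known feature of
bridging-induced attraction).  The affinity sweep uses a 100-bead
homopolymer at c = 0.1 with 3 replicates per affinity.  The full-scale
preset (800 beads, 10 types, 50 σ box, 10⁸ steps, up to 300 replicates)
encodes the published system sizes and runs for hours; it is provided but
not exercised by the default test run.

## Known limitations

* Desk-scale shape statistics are size-dependent: 200-bead collapsed
  conformations are triaxial (mean b/c ≈ 1.3-1.45) rather than
  axisymmetric-prolate (b ≈ c), and their mean ellipticity is accordingly
  lower than for the full-scale system.  See the a/c vs b/c Mann-Whitney
  comparison for the scale-independent statement (the two distributions
  separate sharply).
* The shifted-LJ convention rescales affinity thresholds by ≈ 1.5×
  relative to unshifted truncations (see Potentials).
* Near-threshold sweep points are critically slow; within the desk
  sampling window the apparent threshold is biased upward.
* No hydrodynamics, no bond-crossing bookkeeping, no Hi-C normalisation
  (ICE/KR) — comparison matrices are assumed pre-normalised and dense;
  `.cool`/`.hic` conversion is delegated to external tooling.
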