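# Methods

## The model

A von Willebrand Factor (vWF) multimer is represented as a linear chain
of `N = 100` beads standing for 50 monomers.  Within monomer `i` the
two beads `(2i, 2i+1)` are joined by a finitely extensible nonlinear
elastic (FENE) spring that stands in for the force-sensitive A2 domain,

    F(r) = k r / (1 - (r/R0)^2),

which is linear at small extension and diverges at the maximum
extension `R0`.  Consecutive monomers are joined by a stiff harmonic
bond (the inter-monomer disulfide link).  Non-bonded beads attract
through a truncated Lennard-Jones potential, which collapses the chain
into a compact globule at rest.  An imposed unbounded simple shear flow
`v_x = γ̇ z` (flow along x, gradient along z, vorticity along y) drives
tumbling, intermittent unraveling and internal tension.  An A2 domain
is labeled *unfolded* at an instant when its spring tension strictly
exceeds 11 pN, the most likely unfolding force seen in single-molecule
pulling experiments on the A2 domain (reported range 7–15 pN).

Bead motion is overdamped Brownian dynamics.  By default every bead has
the free-draining Stokes mobility `1/(6π η a)`; a pairwise
Rotne–Prager–Yamakawa mobility with fluctuation–dissipation-consistent
correlated noise is available (`hi_mode="pairwise"`) but is O(N³) per
step and is not used in the production configuration.

## Parameters

All parameters live in `SimParams` with physical units (nm, pN, s, K).
None are experimentally fitted; they are model defaults chosen once to
place the chain in the physically sensible regime at the strong shear
rate of the study, and every one is config-exposed.

| parameter | default | rationale |
|---|---|---|
| bead radius `a` | 12 nm | half-monomer scale of the coarse-grained vWF literature (tens of nm) |
| FENE `R0` | 60 nm | order of the unfolded A2 contour length |
| FENE `k` | 0.0825 pN/nm | soft spring; F = 11 pN at 0.645 R0, so the threshold sits well above thermal tension (~1 pN at rest) |
| harmonic `k` | 4.125 pN/nm | 50× the FENE constant ("stiff" link), rest length one bead diameter |
| LJ depth | 4.0 kBT | with the short 1.5 σ cutoff this holds a stable rest globule (Rg ≈ 45 nm ≪ contour) that still unravels intermittently at the working shear |
| LJ σ / cutoff | 24 / 36 nm | bead diameter; short-range attraction keeps the pair loop cheap |
| repulsion cap | 50 pN | soft-core regularization so hard collisions cannot overshoot at the working timestep |
| shear rate γ̇ | 5×10⁵ s⁻¹ | the study's strong-shear condition; reduced shear γ̇·τ ≈ 3.9 with τ = a²/D ≈ 7.9 µs |
| temperature, viscosity | 300 K, 1 mPa·s | water-like solvent |
| timestep Δt | 1.4×10⁻⁸ s | converged: halving it changes the unfolding fraction by <6% |
| sample interval | 1.96×10⁻⁵ s | ≈ 2.5 bead diffusion times (1400 steps) |

At these conditions roughly 45% of sampled frames contain at least one
unfolded A2 domain, the ensemble-mean tension profile along the contour
is quasi-parabolic (peak at the chain center, little force at the
termini), and unfolding frequency follows the same shape — the
qualitative structure the classifier is meant to learn.

## Numerical scheme

The integrator is Euler–Maruyama with both bonded interactions treated
semi-implicitly by operator splitting: after the explicit update
(non-bonded forces, shear advection, thermal noise), each harmonic bond
relaxes toward its rest length in closed form and each FENE spring's
new length is obtained from a cubic with a unique root in `(0, R0)`.
Because consecutive bonds alternate between the two families and each
family connects disjoint bead pairs, both implicit solves decouple
exactly.  This keeps every spring strictly inside its extensibility
limit at any tension the flow produces — explicit Euler is
unconditionally unstable near `R0` — and removes the stiff-bond
timestep bound.  The implicit relaxation damps harmonic-bond length
fluctuations by roughly `1/(1+2kΔt/ζ)` (~20% here), which is
immaterial for a bond whose role is to fix monomer spacing.

Pair forces use a Verlet neighbor list whose rebuild trigger works in
the shear-co-advected frame: the list is rebuilt when twice the maximum
bead deviation plus the accumulated advective strain across the list
radius could exceed the skin (half a bead diameter).  Kernel state is
float32 — Brownian steps of ~1 nm dwarf single-precision rounding at
the coordinate magnitudes reached — with the FENE cubic solved in
float64.  Chains are seeded from `numpy.random.SeedSequence(root,
replica, stage)`, so identical `(params, seed)` reproduce bit-identical
trajectories and replicas are independent streams.

Equilibration starts from monomer blobs on a compact serpentine lattice
and runs at zero shear until the window-averaged radius of gyration
changes by less than 1% over three consecutive 10⁴-step windows.

## Features, labels, dataset

Each observation is a pair of consecutive sampled frames.  The chain is
partitioned into 1, 5 or 10 equal contiguous contour segments; per
segment the features are COM velocity components (finite difference
over one sample interval), the flow-induced COM displacement
`|γ̇ z̄ Δt_s|`, per-axis maximum spans, end-to-end distance, per-axis
and total radii of gyration, the flow variation fraction
`RG_X/(RG_X+RG_Y+RG_Z)`, the local chain concentration (share of all
beads within 50/10/5 bead radii of the segment COM for the three
resolutions — always half the segment's bead count), and the absolute
flow-direction cosines of the three principal axes of the segment's
position covariance (1/n normalization; degenerate spectra tie-broken
toward x, then y, then z).  The 3N raw bead position components enter
the model individually and are aggregated into three reported indices
(Σx, Σy, Σz) for importance bookkeeping, giving 20 / 88 / 173 reported
feature indices at the three resolutions and 3N + 17·n model inputs.

Labels are the instantaneous per-segment OR of the 11 pN threshold over
the segment's springs; the chain-level label is the OR over all 50
springs.  The dataset balances chain-level classes exactly 50/50 by
seeded sampling without replacement and splits 70/30, stratified on the
chain-level label.  Per-segment imbalance is deliberately preserved —
terminal segments stay scarce in unfolded examples, which is the
phenomenon behind their poor unfolded-class recall.

## Forests and importances

One independent binary random forest per (resolution, segment)
(scikit-learn, Gini splitting, bootstrapped trees, majority vote,
`sqrt(n_features)` candidates per split; tree count config-exposed).
Performance is reported as per-class recall — the fraction of truly
folded (resp. unfolded) test rows predicted correctly.  Importance is
mean decrease in Gini impurity, normalized per forest; raw per-input
importances are aggregated onto the reported feature indices (position
components summed per axis), ranked with segment-of-origin annotation
(cross-segment entries expose correlated segment dynamics), cumulated
over the top k, and unrolled into per-bead, per-axis importance
profiles along the contour.

## Desk-scale study conditions and their limits

The full-scale study behind the reference numbers used 200,000
decorrelated observations; the desk-scale configuration used by the
test suite and `scripts/acceptance.py` (`desk_study_config`) runs 9
replicas × 2750 samples (≈0.49 s of physical time in total,
3.5×10⁷ BD steps, ~14 min on one CPU), draws a 20,000-row balanced
dataset, and trains 60-tree forests only for the segments the headline
quantities need.  If the unraveling statistics of a particular seed
leave one chain-state class short of the 10,000-row quota, the ensemble
is topped up with additional replicas.

Two compromises of this scale must be kept in mind when reading its
numbers:

1. **Residual temporal correlation.**  The measured decorrelation time
   of the total radius of gyration at these conditions is ~25 bead
   times, but the desk-scale pipeline samples every ~2.5 bead times
   (`stride=1`), because fully decorrelated sampling at 20,000
   observations costs ~100 CPU-minutes.  Successive observations are
   therefore correlated, and since the 70/30 split is random over
   correlated rows, test recalls are somewhat optimistic.  The faithful
   rule — stride at least the measured autocorrelation time
   (`estimate_decorrelation_stride`, `stride="auto"`, with a 25% safety
   factor beyond the 0.2-crossing of the autocorrelation) — is
   implemented and verified on cheap synthetic trajectories.
2. **Free-draining mobility.**  Without hydrodynamic shielding the
   terminal segments experience relatively more drag than in a
   hydrodynamically interacting chain, so terminal A2 unfolding, while
   much rarer than central unfolding, is not as vanishingly rare as in
   the reference data (~9% of balanced training rows versus ~0.4%).
   The ordering structure — central ≫ terminal — is robust.

Consequently the desk-scale classifier reproduces the qualitative
results exactly (all recall orderings along the contour, the
quasi-parabolic tension and unfolding profiles, the concentration of
importance in a small feature subset, cross-segment importance entries
for outer segments) while its absolute unfolded-class recalls and
top-14 cumulative importance run 5–20 percentage points below the
full-scale reference values.  What passing tests show about real data
is correspondingly structural, not quantitative: the synthetic
generator contains no measurement noise, no diffraction-limited
blurring, and exactly the physics listed above.

## Degenerate inputs and tie-breaks

FENE evaluation at or beyond `R0` raises a domain error (in a running
simulation this indicates a corrupted external frame, since the
integrator cannot produce one).  A partition collapsed to a point has
`VFF = 0` (with a warning) and PCA projections from the deterministic
axis-preference tie-break.  Importance ranking ties break toward the
lower reported index.  Single-class training targets raise with advice
to sample more densely rather than silently fitting a constant.
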