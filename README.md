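# shearfold

Coarse-grained Brownian-dynamics simulation of von Willebrand Factor
(vWF) multimers in shear flow, and random-forest prediction of
sub-monomer A2 domain unfolding from macromolecular conformation.

vWF is a long multimeric blood protein that senses hydrodynamic force:
under strong shear it unravels from a compact globule, exposing its
force-sensitive A2 domains, whose unfolding gates both platelet binding
and enzymatic size regulation.  `shearfold` is for computational
biophysicists who want to ask: *given only coarse, macromolecular
observables of a sheared chain — the kind of quantities a fluorescence
microscope could plausibly estimate — can the instantaneous
folded/unfolded state of the A2 domains be predicted, and which
observables carry that information?*

The package provides, end to end:

- **Simulation** (`shearfold.simulation`): a 100-bead / 50-monomer
  bead–spring chain.  Each monomer is two beads joined by a FENE spring
  `F(r) = k r / (1 − (r/R0)²)` standing in for the A2 domain; monomers
  are linked by stiff harmonic bonds; attractive Lennard-Jones
  interactions collapse the chain into a rest-state globule; simple
  shear `v_x = γ̇ z` at `γ̇ = 5×10⁵ s⁻¹` drives tumbling and
  intermittent unraveling.  Overdamped dynamics with semi-implicit
  bonded updates (numba-accelerated, bit-reproducible under a seed).
- **Features** (`shearfold.features`): the chain partitioned into 1, 5
  or 10 equal contour segments; per segment COM velocity, flow-induced
  displacement, per-axis spans, end-to-end distance, radii of gyration
  (RG_X, RG_Y, RG_Z, RG_TOT), flow variation fraction VFF, local chain
  concentration LCC, and flow-direction projections of the three
  principal axes — plus the 3N raw bead coordinates; 20 / 88 / 173
  reported feature indices at the three resolutions.
- **Labels** (`shearfold.labels`): a spring is unfolded when its
  tension strictly exceeds 11 pN (the most likely A2 unfolding force in
  single-molecule experiments); segments OR their springs.
- **Dataset** (`shearfold.dataset`): decorrelation-aware observation
  sampling, exact 50/50 chain-state balancing, stratified 70/30 split.
- **Model** (`shearfold.model`): `A2StateModel(dataset).fit()` returns
  `A2StateResults` with per-class test recalls, Gini feature
  importances, ranked cross-segment importance tables, per-bead
  importance profiles and a `summary()` table.

## Worked example

```python
import shearfold as sf
from shearfold.model import A2StateModel, ForestConfig

params = sf.SimParams(n_replicas=2, n_samples=1500, seed=7)
trajs = sf.simulate(params)                      # ~3 min on one CPU

model = A2StateModel.from_trajectories(
    trajs, resolution=5, n_total=2000, stride=1, burn_frames=12, seed=8,
)
results = model.fit()
print(results.summary())
```

prints (numbers vary with seed; this is a deliberately small run):

```
A2 domain state prediction (random forest)
==========================================================
resolution: 5 segment(s)   observations: 2000 (train 1400 / test 600)
trees per forest: 100   model inputs: 385   reported indices: 88
----------------------------------------------------------
target      folded recall  unfolded recall   top-14 cum.
y_s1                0.983            0.390         0.820
y_s2                0.956            0.615         0.769
y_s3                0.980            0.574         0.764
y_s4                0.966            0.621         0.792
y_s5                0.970            0.600         0.776
----------------------------------------------------------
```

Read it as: folded A2 domains are predicted almost perfectly in every
segment; unfolded domains are predicted markedly worse in the first
terminal segment (`y_s1`, recall 0.39) than in the interior, because
internal tension — and hence unfolding — concentrates toward the center
of a sheared chain, leaving terminal unfolded examples scarce.  (At
this small scale the interior segments are statistically equivalent; the
full desk-scale run in the acceptance suite resolves the interior
maximum at the chain center.)  The top-14 column is
the share of total Gini importance carried by the 14 highest-ranked
reported features: a small subset of conformational observables carries
most of the predictive information.  `results.ranked_features("y_s1")`
shows that outer-segment predictions lean on features measured in
*neighboring* segments — correlated segment dynamics.

A YAML-configured CLI wraps the same stages:

```bash
shearfold simulate --config cfg.yaml --out runs/ --replicas 8 --seed 7
shearfold featurize --traj runs/traj_000.h5 --resolution 5 --out feats.csv
shearfold train --dataset feats.csv --resolution 5 --out model/
shearfold run-all --seed 7 --out full_run/
```

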