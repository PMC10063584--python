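# mcfold

Multicanonical dynamic-docking analysis at desk scale: flat-histogram
sampling of coarse-grained binding systems, canonical reweighting, distance-
array PCA free-energy landscapes, cluster-free-energy representative picking
with contact-similarity merging, refinement/stability scoring, and
binding-pathway extraction along a dissociation coordinate.

## The problem

Peptides with intrinsically disordered binding motifs (the BH3 motif binding
the Bcl-xL groove is the canonical case) fold *as* they bind, and their
receptors can hide part of the binding site behind a gate that only opens
once the ligand arrives.  Plain molecular dynamics at room temperature
rarely crosses the barriers separating bound, unbound, open and closed
states.  Multicanonical sampling (McMD) replaces the potential energy E with
a modified energy E_mc(E) chosen so the energy histogram is *flat* across a
temperature range (here 280–700 K): the simulation then random-walks in
energy, repeatedly binding and unbinding, and any canonical ensemble in the
range is recovered afterwards by per-snapshot reweighting

    w_j ∝ exp[ E_mc(E_j)/(R·T_mc) − E_j/(R·T) ].

From the reweighted ensemble the pipeline builds the analyses used in
dynamic-docking studies:

* a 2-D free-energy landscape PMF_i = −RT ln P_i over the first two
  principal components of an intermolecular distance array;
* K-means clusters ranked by **cluster free energy** CFE = −RT ln P_k, with
  one representative per cluster and near-duplicates merged when they share
  more than 70% of their intermolecular contacts (the **R-value**);
* canonical refinement of each representative and a two-temperature
  (300/400 K) stability score (mean R against the starting pose);
* a connected binding pathway along the dissociation coordinate λ (the
  ligand COM position along the exit axis), picking per λ-window the
  snapshot most contact-similar to the previous pick;
* structural observables: DSSP-style secondary structure and helicity
  profiles, Shrake–Rupley solvent accessibility (RASA), and pocket-width
  distances.

The package ships synthetic study systems with analytically known answers —
a quartic double well with quadrature oracles, planted multi-modal ensembles
with exact cluster masses, and a coarse-grained "cryptic pocket" toy whose
gate, binding sites (P1–P4) and coupled folding are all planted — so every
stage is testable without any external data.

## Worked example

```python
import numpy as np
from mcfold import synth, engine, reweight
from mcfold.constants import R_KCAL

# a particle in a quartic double well, barrier 3 kcal/mol, tilt 1 kcal/mol
system, oracle = synth.make_double_well(3.0, asymmetry=1.0)

# flatten the energy histogram over the 280-700 K range, then sample
cfg = engine.McMDConfig(base_seed=3, n_parallel=20, save_interval=2,
                        bin_width=0.05)
bias, _, diag = engine.calibrate_bias(system, cfg)
production = engine.run_mcmd(system, bias, 10_000, seed=99, n_walkers=20,
                             save_interval=2)

w = reweight.canonical_weights(production, bias, 300.0)
left = w.weights[production.coords[:, 0, 0] < 0].sum()
print(f"frames: {len(production)}  ESS at 300 K: {w.ess:.0f}")
print(f"lower-well population (sampled): {left:.3f}")
print(f"lower-well population (quadrature): {oracle.well_populations(300.0)[0]:.3f}")
```

Output from this exact script:

```
frames: 100000  ESS at 300 K: 20561
lower-well population (sampled): 0.835
lower-well population (quadrature): 0.831
```

The 100 000 multicanonical frames span the whole 280–700 K energy range in
one run; reweighted to 300 K they reproduce the quadrature answer (the
Boltzmann ratio across a 1 kcal/mol offset, ~0.84/0.16) to the third digit,
with an effective sample size of about 20 000.

The full pipeline — sampling, landscape, representative picking, stability
and pathway — runs from one config:

```bash
mcfold run --out results/ --seed 1
```

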