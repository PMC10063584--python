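# Methods

This note records the models, the numerical choices and the limits of the
synthetic study systems.  Units throughout: kcal/mol, Å, K;
R = 1.98720425864083e-3 kcal/mol/K.

## Sampler

The engine is Metropolis Monte Carlo with Gaussian single-particle moves
(default step 0.25–0.35 Å), vectorized across independent walkers; one
named generator per trajectory is seeded from (base seed, walker index), so
every run is bitwise reproducible per trajectory and walker streams are
independent of how many walkers run.  Thermostats, barostats and explicit
solvent are out of scope: Metropolis acceptance gives exact canonical
targets, which is what the test oracles need.  An overdamped-Langevin
integrator is provided as an alternative; every potential term carries
analytic forces kept consistent with central finite differences to 1e-5
relative.

"Sweeps" (one attempted move per mobile particle) are the time unit.
Protocol durations quoted in nanoseconds for all-atom work map onto sweep
counts here; the standard conditions used by the tests and the acceptance
script are stated below as the package's study sizes.

## Multicanonical bias

Supported range and construction:

* **Initial estimate.**  From a canonical run at T_high = 700 K the density
  of states along energy is estimated from the histogram,
  ln n(E) = ln P(E, T_high) + E/(R·T_high), and the modified energy is
  E_mc(E) = R·T_high·ln n(E) (an additive constant is irrelevant).  Sampling
  with E_mc at T_mc = T_high then targets a flat energy histogram.
* **Representation.**  E_mc is a monotone piecewise-cubic (PCHIP) fit
  through the binned values; monotonicity is enforced by a running maximum
  on the knot values before fitting.  Outside the fitted range the curve
  continues linearly with the boundary slopes, floored at 1: a tail slope
  below 1 would make the effective temperature T_mc/slope exceed T_mc and
  let the sampler run away up an unbounded potential.
* **Update.**  Each iteration adds R·T_mc·ln P_obs(E) to the modified
  energy, penalizing over-sampled energies; a flat histogram is a fixed
  point (constant shift).  Empty bins inside the sampled range are bridged
  by linear interpolation of ln P with a warning.  Optional Savitzky–Golay
  smoothing of the binned values exists but is off by default — the
  monotone fit already regularizes, and smoothing was found to blur exactly
  the structure the update must remove.
* **Flatness.**  Measured as the max/min histogram-count ratio over the
  target canonical range [⟨E⟩(T_low), ⟨E⟩(T_high)], with the range itself
  estimated by reweighting the current production run (tolerance 1.2).
* **Bin width.**  The config default is 0.5 kcal/mol; the double-well test
  systems use 0.05–0.1 kcal/mol because their whole canonical range spans
  under one kcal/mol.  One-dimensional systems have inverse-square-root
  density-of-states singularities at well bottoms that a smooth monotone
  fit cannot flatten to the 1.2 tolerance; the two-dimensional double well
  (smooth density of states) is therefore the flatness test system, and the
  one-dimensional well is used for the reweighting oracle, which does not
  require perfect flatness.

## Reweighting

Per-snapshot weights w_j ∝ exp[E_mc(E_j)/(R·T_mc) − E_j/(R·T)], normalized
by log-sum-exp.  Weights are per snapshot, not per energy bin, so landscape
and cluster probabilities are plain weight sums with no double-binning bias.
The Kish effective sample size 1/Σw² is always available and a warning fires
below ESS = 100.  Snapshots from all trajectories are pooled before
reweighting (single bias, shared T_mc); per-trajectory renormalization is
not applied.

## Landscapes, clustering, merging

* PCA is computed on the **unweighted** multicanonical distance array (the
  eigendecomposition of the column covariance); reweighting enters only
  through the bin probabilities P_i on the landscape.  The component-sign
  convention (largest-magnitude loading positive) makes scores bit-for-bit
  reproducible.
* PMF_i = −RT ln P_i with the occupied minimum shifted to zero and a 5
  kcal/mol display cutoff.  The default grid is 100×100 bins padded 2%.
* K-means (k-means++, 10 restarts, fixed seed) runs on the leading
  components whose cumulative variance contribution exceeds 90%.  The
  desk-scale default is k' = min(1000, n/10) because k' = 1000 presumes
  millions of snapshots.
* CFE = −RT ln P_k, ranked ascending and min-shifted.  Merging walks the
  ranking from the most stable cluster: a candidate whose R-value against
  any retained representative exceeds 0.7 is merged into the first such
  match (first match in rank order — deterministic), masses added, CFEs
  recomputed.  The retained representative keeps its own snapshot.
  Representatives with CFE below 2.5 kcal/mol form the stable set.

## R-value and RMSD

A contact is a heavy-atom pair within 4.5 Å; intramolecular contacts
exclude same-residue and |Δres| ≤ 2 pairs; intermolecular means spanning
different *molecules* (chain roles where declared — a receptor built from
several chains counts as one molecule).  R(query | ref) is the fraction of
the reference's contacts present in the query: asymmetric by construction,
1 for self-comparison.  The per-residue decomposition assigns each contact
to both participating residues, so the contact-weighted mean of per-residue
values equals the global R exactly.  The atom-pair-level set definition and
the 4.5 Å cutoff are configurable choices: the metric's published uses fix
only its identity, range and decomposition properties, all of which hold
here.  RMSD uses Kabsch (SVD) superposition; ligand RMSD is reported in the
receptor-fixed frame (fit on receptor atoms, deviation over ligand heavy
atoms), the same frame in which λ is defined.

## Pathway extraction

λ is the mass-weighted ligand-COM coordinate along the dissociation axis.
The λ range splits into contiguous windows (default width 2.5 Å — over the
−2.5 to 40 Å restrained range of the motivating system this yields 17
windows).  Starting from the bound reference in the first window, each
window's pick maximizes R against the previous pick; ties break by lower
ligand RMSD, then lower frame index, so paths are deterministic.  Once the
previous pick has no intermolecular contacts (unbound region) R is
undefined and the pick falls through to the RMSD rule.  Steps with R below
0.6 are flagged as putative barriers.  No free-energy pre-filtering is
applied to window candidates.

## Refinement and stability

Representatives are refined by n independent canonical runs started from
them with the sampling-era restraints removed; "final 40 ns of 100 ns"
generalizes to the final 40% of each trajectory.  q_k is the pooled-final-
segment frame nearest the mean coordinates (ligand heavy atoms in the
receptor frame by default; configurable).  Stability at each probe
temperature (300 K and 400 K) is the across-trajectory mean and standard
deviation of the per-trajectory mean R against the starting pose over the
final segment, reported as "mean (sd)".

## Secondary structure and surfaces

Secondary structure follows Kabsch–Sander: H-bond energy
0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN), bond below −0.5 kcal/mol,
amide H placed 1 Å from N opposite the preceding carbonyl when absent;
α-helix (H) from two consecutive i→i+4 turns, 3₁₀ (G) from i→i+3 turns,
strand (E) from parallel/antiparallel bridges, priority H > E > G; π-helix,
turns and bends collapse to C.  Helicity counts class H only — the
strictest reading; switching to H+G is a one-line change.  Agreement with
an independent DSSP implementation is held at ≥98% over generated
helix/3₁₀/strand/coil fixtures built from ideal backbone geometry.

SASA is Shrake–Rupley with a deterministic golden-spiral point set (960
points by default; rotation invariance holds to the point-set resolution,
~0.5%) and Bondi radii.  RASA divides the ligand's in-complex SASA by the
SASA of the *same conformation* isolated, making it a pure burial measure;
an extended-chain reference would mix burial with conformational change.

## Synthetic study systems

* **Double well** (1-D/2-D): U = b(x²−1)² + δx/2 (+ y²), b = 3 kcal/mol ≈
  5.4 R·T_low so the 280–700 K range spans rare-to-frequent barrier
  crossing.  The oracle computes populations, energy CDFs and 2-D PMFs by
  dense-grid quadrature, independent of the sampling code.
* **Cryptic toy** (2-D): four Gaussian attraction sites (depth 2.5
  kcal/mol, spacing 3 Å; P1 innermost, P4 at the mouth), a gate bead in a
  double well along y whose closed position clashes sterically with ligand
  beads at P1/P2 (closed favored by 1.2 kcal/mol when unobstructed), a
  5-bead ligand chain whose angle stiffness grows with site occupancy
  (base 0.15, +0.8 kcal/mol per unit occupancy — coupled folding and
  binding), and flat-bottom COM restraints confining λ.  Enumeration over a
  discretized configuration grid confirms the global minimum is
  bound + gate-open + folded.  Ground-truth labels: bound = λ < 10 Å,
  open = gate y above the barrier top, folded = mean chain straightness
  > 0.8.  Standard study conditions: 20 trajectories, calibration schedule
  (1500, 1500, 2000, 2000, 3000, 3000, 4000, 4000, 5000) sweeps, 30 000
  production sweeps saved every 5.
* **Planted ensembles**: modes are ligand-bead→site maps realized as
  coordinates with 0.2 Å jitter; frames are allocated evenly across modes
  and each mode carries the constant energy that makes its 300 K canonical
  weight equal the planted mass exactly (identity bias at T_mc = 700 K), so
  cluster-free-energy recovery is exact up to clustering error.  The
  five-mode layout plants exactly one pair sharing >70% of contacts for the
  merge test.
* **Funnel**: the native pose rigidly drawn outward along λ with small
  jitter — a smooth planted pathway for the window-picking oracle.

What the toys do **not** emulate: solvent and friction, realistic
force-field energetics and entropy scales, rotational diffusion of the
ligand, receptor flexibility beyond the single gate, and the sheer
dimensionality of all-atom ensembles.  Passing tests therefore validate the
*machinery* — flattening, reweighting, landscape/cluster/merge bookkeeping,
pathway picking, observable definitions — not any quantitative claim about
real protein systems.

## Degenerate inputs and tie-breaks

Empty clusters are flagged and excluded from CFE tables; representatives
without contacts in scope never merge (R undefined is treated as
dissimilar); empty λ windows raise an error naming the bounds; nearest-to-
centroid and pathway ties break to the lowest snapshot index; histogram
values outside the bin range accumulate in an overflow counter rather than
being silently clipped.

## Known limitations

* The Metropolis engine is not aimed at kinetics; "trajectories" order
  configurations but carry no physical time.
* Single-bias reweighting only; combining runs under different biases
  (WHAM/MBAR) is out of scope.
* The flat-histogram construction assumes a one-dimensional collective
  energy; systems whose relevant slow coordinate is orthogonal to energy
  will mix slowly regardless of flatness.
* Sphere-point SASA and the DSSP port trade sub-percent accuracy for
  determinism and zero dependencies.
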