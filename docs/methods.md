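# Methods

## The prediction problem

Proteins that bind DNA or RNA do so through surface patches whose shape,
chemistry, and electrostatics are complementary to the nucleic acid.
`surfbind` models a protein as a triangulated molecular-surface mesh
`G = {V, E}` with per-vertex features `X_V` and per-edge features `X_E`, and
answers two questions with graph neural networks:

* **Binding function** (classification): does this protein bind nucleic
  acid?  A single Bernoulli probability per mesh.
* **Binding site** (segmentation): which surface vertices belong to a
  binding site?  A Bernoulli probability `q_i` per vertex, max-pooled over
  each residue's surface patch to give residue-level predictions.

Both models are trained by minimizing the cross-entropy between predicted
probabilities and observed binary labels, summed over graphs (and vertices,
for segmentation), with Adam and early stopping on validation loss.

## Surface meshes

The production route in the field uses a solvent-excluded or "skin" surface
from an external generator; such meshes are imported through the OFF/PLY
readers and are first-class inputs (the generator's shrink factor can be
recorded as metadata).  The in-repo generator samples a Gaussian atomic
density `rho(x) = sum_i exp(-(|x - x_i|^2 - r_i^2) / sigma^2)` on a regular
grid and triangulates the `rho = 1` isosurface with marching cubes, so an
isolated atom's surface sits exactly at its van der Waals radius.  This
preserves pocket and protrusion geometry at desk scale without an external
binary.  Atomic radii follow an AMBER-style element table; hydrogens whose
table radius is zero are assigned a 0.6 A floor.  Faces are oriented
outward by a per-component signed-volume test, since the sign convention of
the curvature feature depends on it.  Every vertex is mapped to its nearest
atom and that atom's residue; atom-level features are transferred to
vertices by inverse-distance weighting within 2.5 A (nearest-atom fallback
beyond).

## Vertex and edge features

Eighteen structure-based vertex features:

| group | columns | definition |
|---|---|---|
| electrostatics | PH1, PH2 | screened-Coulomb (Debye-Hueckel) potential and outward-normal field component at 0.15 M ionic strength; see below |
| Atchley factors | AF1-AF5 | five physicochemical factors per residue, broadcast to atoms |
| hydrophobicity | SAP | spatial aggregation propensity: Black-Mould hydrophobicity (centred on Gly) x relative side-chain exposure, summed over side-chain atoms within 5 A |
| hydrogen bonding | HBA, HBD | indicator of proximity to acceptor/donor heavy atoms |
| burial | CV1-CV3 | circular variance of unit vectors to atoms within 7.5 / 15 / 30 A; ~0 on protrusions, ~1 in pockets |
| curvature | MC | discrete mean curvature (cotangent Laplacian, mixed Voronoi areas); convex positive |
| shape | HK1-HK4 | heat kernel signatures at four diffusion times spanning ~3-20 A effective diffusion distance, min-max normalized per mesh |

When PSI-BLAST ascii PSSMs and HHblits `.hhm` profiles are supplied they are
parsed (never executed) into 50 additional per-residue columns: PSSM
log-odds logistic-squashed to (0, 1); HHM integer codes decoded via
`p = 2^(-code/1000)`.  Binding-function models use the 18 structural
features only.

Edge features are the edge length and three angles (edge vs. normal at
either endpoint, normal vs. normal), in degrees.  All features depend only
on distances and angles, so every model output is invariant to rotations,
translations, and vertex permutations; this is verified by direct test.

**Electrostatics substitution.**  The reference pipeline solves the
Poisson-Boltzmann equation with a boundary-integral solver (interior
dielectric 2.0, 0.15 M ions).  No such solver is a dependency here, so the
in-repo model is the screened Coulomb potential in a uniform dielectric of
78.5 with the Debye length set by the 0.15 M ionic strength, over a
simplified ionizable-group charge model (Asp/Glu −1, Lys/Arg +1, phosphate
−1, split over equivalent atoms).  Per-vertex potentials from an external
solver can be imported, in which case the column provenance is marked
`imported`.  The interior dielectric is carried in the configuration for
that import path.

**SASA.**  Side-chain exposure uses Shrake-Rupley SASA (biotite) evaluated
in a canonical principal-axes frame, because a fixed point-grid SASA is not
otherwise rotation-invariant.

## Network architecture

Both networks share an encoder that coarsens the mesh `d = 3` times.  At
each level:

1. **FPS pooling** — farthest-point sampling keeps a fraction `alpha = 0.5`
   of vertices as centroids.  The greedy selection breaks distance ties to
   the lowest index; the start vertex is the point farthest from the cloud
   centroid, which keeps the selection invariant to vertex permutation and
   rigid motion on generic inputs (on exactly symmetric meshes the argmax
   is resolved by floating-point noise, so bit-level invariance is only
   guaranteed for generic clouds).
2. **Radial graph** — directed edges join every vertex within `r` of a
   centroid to that centroid, `r = 5.0, 7.5, 10.0 A` per level.
3. **Two crystal-graph convolutions** — for edge `j -> i` the message is
   `sigmoid(z W_f + b_f) * softplus(z W_s + b_s)` with
   `z = [x_i, x_j, e_ij]`; incoming messages are aggregated by a learned
   linear combination of min, max, mean, and population-stdev pooling, and
   added to the centroid's current activation (residual).  Centroids with
   no neighbours pass through unchanged.

For segmentation, a graph-U-Net decoder restores full resolution: features
are interpolated with inverse-distance-weighted `k = 3` nearest-centroid
unpooling, concatenated with the skip activations of the matching encoder
level, mixed by a linear layer, and finally passed through a two-layer MLP
and softmax.  For classification, the coarsest activations are aggregated
by global attention pooling `r = sum_i sigma(f(x_i)) x_i` (`f` a small
MLP), followed by an MLP head and softmax.  The head divides the pooled
vector by the number of pooled nodes — a fixed input scaling that keeps
logits O(1) for any mesh size; the pooling formula itself is the exact sum.

Hidden width defaults to 32 and is configurable; the desk-scale experiments
in the test suite use width 16, which trains in tens of seconds per model
on one CPU at ~642-vertex meshes without changing any conclusion.

The networks run on a small in-repo reverse-mode autodiff engine (numpy).
Per-segment reductions over edges are executed through pre-sorted
`reduceat` plans computed once per mesh alongside the FPS/radial-graph
hierarchy, which is what makes CPU training practical.

## Training, calibration, thresholds

Training is full-graph Adam (default lr 5e-3, mesh minibatches of 4) with
early stopping on validation loss (patience 10 by default; the experiments
use 8) and restoration of the best-epoch parameters.  `crossval_ensemble`
implements stratified k-fold cross-validation (k = 5): per fold, several
random-initialization replicates are trained and the best by validation
loss is kept.  Each kept segmentation model receives Platt scaling
(`p = sigmoid(a s + b)`, Newton iteration on Platt's regularized targets,
slope constrained positive so calibration is order-preserving) fitted on
its validation fold, and an individual decision threshold maximizing F1 on
its training split (candidates are the unique predicted probabilities;
ties resolve to the largest threshold).  Classification models use a fixed
threshold of 0.5, appropriate for balanced function datasets.  Ensemble
predictions are the mean calibrated probability, with labels by majority
vote of the members' own thresholded calls.

Binding-site labels for structures with a bound nucleic acid use the
distance rule: a residue is positive iff any of its atoms is within 5.0 A
of any nucleic-acid atom, and vertices inherit their residue's label.
(Interaction-database annotations used by some benchmark sets are out of
scope; the distance rule is applied uniformly.)

Residue probabilities are max-pooled over each residue's surface vertices;
residues with no surface vertices are flagged buried and excluded from the
residue table.

## Attribution

**Grouped permutation importance** permutes a named group of feature
columns along the vertex dimension (one shared permutation per mesh per
round, preserving within-group covariation) and reports the change in
AUROC; negative importance means the group mattered.  Note an asymmetry
the planted experiments expose: vertex-permutation destroys a
*segmentation* model's signal completely (importance below −0.2 here), but
a *classification* model that pools globally can still detect "elevated
values somewhere on this mesh" after permutation, so its importance values
are small — the ranking across groups, not the magnitude, is the readout
for classification.

**Grad-CAM** differentiates a target class probability with respect to the
activations of a chosen convolution level (default: the final, coarsest
level).  The default scoring is standard Grad-CAM — channel-averaged
gradients weight the activation maps — because the plain channel-averaged
gradient without activation weighting localizes markedly worse (channel
gradients cancel); that variant remains available as
`weight_by_activation=False`.  Scores are rectified, interpolated to the
full mesh by the same k = 3 unpooling the networks use, min-max normalized
per protein, and thresholded at the 75th percentile to define the
high-attribution mask (ties trimmed so the mask is 25% of vertices ± 1).
`high_attribution_features` summarizes feature distributions inside versus
outside the mask.

## The planted-signal generator

Real training corpora (hundreds of co-crystal structures, or thousands of
predicted structures with database-derived labels) are not reproducible at
desk scale, so the test bed is a generator that emulates the statistical
structure the networks exploit: smooth, spatially correlated vertex
features on a protein-sized closed surface, with a contiguous patch whose
designated feature group is shifted.

Defaults, chosen once as the study conditions: 50 meshes (40 train /
10 test); icospheres of ~642 vertices at radius 16 A (a small domain);
patch geodesic radius 15 A, i.e. ~20% of the surface, a realistic binding
footprint; features are unit-variance Gaussian fields smoothed by 3 rounds
of 1-ring averaging; the electrostatics group (PH1, PH2) is shifted by
+2 SD inside the patch.  Patch centres are drawn area-uniformly on the
sphere — drawing them from mesh vertices would bias patches toward the
denser regions of the icosphere triangulation and leak label information
through local vertex density (a no-effect model then beats chance).
Segmentation labels are patch membership; classification labels are patch
presence, with patches planted on half the meshes.

What the generator does *not* emulate: real surface geometry co-varying
with chemistry (its meshes are spheres, so geometric features carry no
signal), profile features, multi-chain assemblies, and label noise from
crystal contacts.  Passing the planted-recovery tests therefore shows that
the architecture, training loop, calibration, and attribution machinery
work end to end on data of the right statistical shape — not that the
trained toy models transfer to real proteins.

## Numerical choices and degenerate inputs

* Cross-entropy probabilities are clamped at 1e-7.
* Segment stdev uses the population convention; a single message gives 0,
  and empty neighbourhoods are masked to an exact residual passthrough.
* The Laplace-Beltrami operator uses cotangent weights with mixed Voronoi
  vertex areas (barycentric thirds misestimate curvature by ~15% at the 12
  irregular-valence vertices of an icosphere; mixed areas bring the sphere
  error under 5% everywhere).
* KNN unpooling copies a coincident centroid's features exactly
  (d < 1e-8); vertex-atom coincidences copy the atom value; electrostatic
  distances are clamped at 0.1 A.
* Zero-area faces are skipped (with a warning) in normal computation;
  coincident edge endpoints and non-triangular faces are hard errors.
* All randomness (dataset generation, initialization, batching, start
  indices when explicitly seeded) flows from explicit integer seeds;
  training is bit-reproducible for a fixed seed.

## Problem sizes used by the test suite

The acceptance experiments train three networks (segmentation at effect
+2 SD and 0 SD, classification at +2 SD) at hidden width 16 on 40 meshes
each, evaluate on the held-out 10 plus a 30-mesh attribution evaluation
set, and finish in a few minutes on one CPU.  Analytic geometry checks use
icospheres up to 2562 vertices and a 100k-sample Monte-Carlo circular-
variance oracle.
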