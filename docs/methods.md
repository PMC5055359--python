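# Methods

This note documents the models, conventions and numerical choices behind
`pknet`, and what the synthetic data do and do not establish about real
confocal reconstructions of the distal Purkinje network.

## The data model

A **centreline network** is an undirected spatial graph: nodes are landmarks
(μm coordinates, RAS frame) placed at furcation points, pathway waypoints and
terminals; edges are straight segments whose length is the Euclidean
distance.  Node roles follow degree: terminal (1), pass-through (2),
furcation (≥ 3).  A **branch** is a maximal chain of edges whose interior
nodes all have degree 2 — the run of connected cells without any furcation;
pure degree-2 cycles are reported as one closed branch and flagged.  A
**cell** is a closed, consistently outward-oriented triangle mesh.

## Cell morphometry

* Surface area is the sum of triangle areas (half cross-product magnitudes);
  degenerate zero-area faces count as zero and are tallied in a warning.
* Volume uses the divergence theorem, `V = Σ_faces v₁·(v₂×v₃)/6`.  It is
  exact for closed oriented surfaces and meaningless for open ones, so open
  meshes raise (with the boundary-edge count) rather than silently repair.
  Validation compares against a voxel-centre counting oracle at the 0.31 μm
  confocal voxel pitch (2 % band) and analytic sphere/capsule values.
* Principal axes come from an SVD of **area-weighted** face centroids
  (vertex-count weighting would bias toward densely tessellated regions).
  Length is the extent along the first axis for tubular cells and the
  longest chord (convex-hull diameter) for star-like cells — for stars with
  symmetric arms the in-plane SVD is degenerate and the first-axis extent is
  not well defined, while the longest chord matches the "longest trajectory
  between borders" convention directly.
* Tubular diameter: the transverse subspace of a cylinder is equally
  degenerate, so the reported diameter is the mean of the transverse
  projection's maximum width (hull diameter) and minimum width (rotating
  calipers).  Both are basis-invariant, making the result stable under
  rigid motion to ≤ 1e-6 relative — extents along arbitrary SVD transverse
  axes are not.

## Synthetic networks

The generator grows trees branch by branch and is the package's definition
of "Purkinje-like":

* **Branch lengths** are i.i.d. draws from an exponential redrawn above a
  cut-off (default 300 μm).  The underlying scale is calibrated (Brent root
  find) so the *truncated* law's mean equals the configured mean, 84.6 μm by
  default.  An uncalibrated exponential with scale 84.6 would realise a
  truncated mean of ≈ 75.7 μm.  With calibration the truncated median lands
  at ≈ 64.8 μm, close to the observed 65.6 μm — the plain exponential's
  58.6 μm median was a known mismatch.
* **Furcation geometry.**  At a 'Y', the daughter–daughter angle is an acute
  draw α ~ N(55.2°, 20.6°) and the two parent–daughter angles are obtuse
  draws β ~ N(140.19°, 25.8°).  Because 55.2 + 2·140.19 ≠ 360, the three
  angles cannot be realised in a plane; they *can* be realised in 3D
  whenever the spherical triangle inequalities |β₁−β₂| ≤ α and
  α+β₁+β₂ ≤ 360° hold.  Daughters are therefore placed at polar angles β₁,
  β₂ about the reversed parent direction with the azimuthal separation
  solved from the spherical law of cosines, plus a uniform random rotation
  about the parent axis.  Infeasible draws (≈ a quarter at the defaults) are
  least-squares projected onto the feasible cone.
* **Circular-normal draws** outside [0°, 180°] are reflected (a 190° draw is
  the 170° line angle), not redrawn; redraw-truncation biases the β mean by
  about −3.4°.
* **Calibration of draw means.**  Reflection, feasibility projection and
  classification of extracted angles by the 90° boundary each shift the
  realised population means a little.  The two draw means are therefore
  calibrated once per parameter set by a deterministic fixed-point iteration
  on the vectorised draw → reflect → project → classify pipeline (fixed
  internal stream, 60 000 draws, 6 iterations), so the *extracted* acute and
  obtuse circular means match the configured values; residual bias is well
  under 1° with per-network sampling scatter of ~1–2° at 500 branches.
* **Growth.**  Each tip grows one branch; with probability `furcation_prob`
  (default 0.45, sub-critical so trees die out and regrow like plexus
  patches) the new node furcates into two daughters.  When all tips have
  terminated before the branch budget is spent, a random terminal is
  re-activated with a forced furcation, so every internal node is a
  furcation and extracted branches coincide with generated edges — the
  configured laws are then recovered exactly.  New nodes keep at least one
  voxel (0.31 μm) away from existing ones (lengths are redrawn in the rare
  collision), matching the landmark-file invariant.
* The **bounding box** (default 318 × 318 × 60 μm, the confocal field of
  view) sets the spatial origin and scale but is not enforced as a hard
  wall: clipping branches at a 60 μm slab would truncate the very length and
  angle laws the generator is supposed to realise.  Real stacks crop the
  field instead; this is a deliberate difference from real data.
* Optional loop closure (`loop_closure_prob`, default 0) connects terminals
  to their nearest non-neighbour, emulating redundant plexus paths.  There
  is no observation-based default for this rate.

What passing the recovery tests shows: the generator realises its configured
statistics, and the extraction code measures them back faithfully.  What it
does not show: anything about segmentation quality, imaging noise,
point-spread functions, or the true spatial correlation structure of
Purkinje pathways — none of which are modelled.

## Synthetic cells

Tubular cells are capsules (cylinder of length L−d plus hemispherical caps,
d/2 radius); `mesh_resolution` r gives 4·2^r azimuthal sections (volume
within 0.2 % of analytic at r = 4).  Star-like cells radially deform an
icosphere: a hub ellipsoid flattened along the coronal axis plus `n_arms`
(default 3) tapering arms in the sagittal plane, with elliptical arm
cross-sections sharing the hub's flattening ratio.  A single-valued radial
surface cannot self-intersect, and the icosphere topology guarantees a
closed genus-0 mesh.  The in-plane scale is normalised numerically so the
longest chord equals the configured length exactly.  The random "blob"
(low-order radial modulation of an icosphere) exists purely as validation
geometry for the volume estimators.

## Graph metrics

Weighted mode uses the Euclidean edge length as connection length (the
inverse-distance weight convention: shortest paths minimise summed length);
binary mode sets lengths to 1.  All-pairs shortest paths are delegated to
`scipy.sparse.csgraph`; the metrics built on them are implemented here and
cross-checked in tests against brute-force path enumeration and networkx
(≤ 1e-9):

* Global efficiency: mean of 1/d over ordered pairs, 1/∞ = 0.
* Local efficiency: per node, the global efficiency of the subgraph induced
  by its neighbours with paths confined to that subgraph; < 2 neighbours → 0.
  Binary mode uses a dense boolean BFS per neighbour set for speed.
* Betweenness: Brandes' algorithm with Dijkstra sources, fractional counting
  over equal-length shortest paths (float equality, the standard
  convention), normalised by (n−1)(n−2)/2.
* Assortativity is computed on binary degree (not strength) as the Pearson
  correlation over the symmetrised edge–endpoint list; zero degree variance
  returns NaN with a defined-flag.
* Characteristic path length averages finite distances only and reports the
  unreachable-pair count separately; disconnected pairs contribute zero
  efficiency.  Whether to analyse components separately is left to the
  caller (the small-world test refuses disconnected input outright).

## Null models and the small-world criterion

Random surrogates: double-edge swaps with a success target of 10 per edge
(attempt cap 10×), rejecting self-loops and multi-edges — degree sequence,
edge count and the weight multiset (shuffled onto new edges) are conserved
exactly.  A uniformity check on the path graph P10 verifies the sampler
visits path-plus-cycle configurations at their exactly enumerated rate.

Lattice surrogates accept a swap only when it strictly reduces the
adjacency-band cost Σ|rank(i)−rank(j)| under a breadth-first node ordering
from the highest-degree node.  Acceptance collapses as the band tightens,
so the attempt cap is 30× the success target; the tail of the descent is
what makes the surrogate lattice-like (on Watts–Strogatz test graphs the
binary local efficiency of surrogates rises from ≈ 0.6 to ≈ 0.73–0.78 in
that tail while global efficiency falls well below the original's).

The verdict requires both strict orderings `GE_latt < GE < GE_rand` and
`LE_rand < LE < LE_latt` over ensemble means (default 100 + 100 surrogates).
Graphs with fewer than 4 nodes or 2 edges report *indeterminate* rather than
false.  Two degenerate cases calibrate expectations: a ring lattice is
(near) its own lattice optimum, so at least one inequality fails essentially
always; a fully randomised graph is exchangeable with its own random
ensemble, so each marginal inequality is close to a fair coin and the
conjunction holds only ~25 % of the time — the acceptance tests therefore
assert a strict-majority false rate for these cases, not certainty.  The
test batteries use 25-surrogate ensembles: the verdict margins on the test
graphs exceed 0.1 while the standard error of a 25-surrogate mean is below
0.005.

## Statistics

Circular mean is the direction of the summed unit vectors; circular SD is
√(−2 ln R̄) in degrees, with R̄ ≈ 0 flagged as undefined direction.  Linear
mean ± SD is reported alongside since published angle summaries are often
linear; for these concentrated samples the two differ by well under a
degree.  The across-stack comparison is a one-way ANOVA (scipy) at
α = 0.05; identical groups are reported as F = 0, p = 1.  Boxplots use
linearly interpolated 25th/75th percentiles with whiskers at the extremes.

## Determinism

Every stochastic routine takes a seed or Generator.  The pipeline spawns one
`SeedSequence` substream per (stack, stage) pair, so adding a stack never
perturbs another's results, and identical configs reproduce byte-identical
CSV/JSON outputs.  The angle-mean calibration and the lattice node ordering
are deterministic by construction.

## Problem sizes

Test batteries run at sizes chosen to make their statistical claims sharp
but cheap: brute-force oracle graphs at n ≤ 12 (50 graphs) and library
cross-checks at n ≤ 30 (100 graphs); generator recovery at 500 branches
(3 SE ≈ 11 μm for the length mean, ~1–2° scatter for angle means);
distributional checks at 1000 branches × 100 seeds; small-world verdict
rates at 100 master seeds (Watts–Strogatz n = 100, k = 6) with 25-surrogate
ensembles, and 25 master seeds for the two degenerate controls.  The
analysis drivers use 16 stacks of 8–120 branches and 100 + 100 null
ensembles, mirroring a realistic study layout.

## Known limitations

* The generator's trees have no spatial self-avoidance beyond the one-voxel
  node separation; pathways may cross in space as drawn centrelines do.
* Star-like cells with symmetric arms make the in-plane principal axes
  degenerate; the reported sagittal diameter is then the second-axis extent,
  which reflects arm span rather than hub width, and is not
  rotation-stable (length and coronal thickness are).
* Latticisation is greedy descent, not an optimal banding; its ensembles are
  "lattice-like", which is the convention this style of analysis uses, not
  certified minima.
* The STL writer inherits float32 precision from the format; PLY (float64)
  is the default for lossless roundtrips.
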