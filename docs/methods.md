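# Methods

This note documents the models, algorithms and numerical choices behind
`neurodecomp`, in the spirit of a methods section: what each stage
assumes, which knobs matter, and what the synthetic benchmark does and
does not establish about real data.

## Coordinate and unit conventions

All geometry is in nanometres. Densities are quoted per micrometre of
skeletal length and converted exactly once, at parameter intake. The SWC
writer alone emits micrometres (the de-facto NeuroMorpho convention:
space-separated columns `id type x y z radius parent`, `#` comments, type
codes 1 soma / 2 axon / 3 basal / 4 apical / 0 undefined).

## Synthetic neurons

The generator grows a skeleton outward from a spherical soma (default
radius 5 µm): an axon stem (radius ≈ 280 nm) heading along the depth
axis, an apical trunk (≈ 1.2 µm) heading toward the pia for excitatory
cells, and basal stems (≈ 0.9 µm) fanning out laterally. Segments are
15–30 µm long with a small direction wiggle per 2 µm step (σ = 4°),
taper to 75% of their initial radius, and branch into two children with
25–50° deviation. Radii are monotone non-increasing away from the soma by
construction, which is exactly the property that width-jump proofreading
exploits.

Spines are scattered on dendrites as a Poisson process (default
1 spine/µm, matching the spiny-benchmark condition). Mushroom spines have
a head of radius 250–500 nm on a neck of radius 80–150 nm and length
0.5–2 µm; stubby spines are hemispheric bumps of radius 300–600 nm. The
resulting true "skeletal lengths" (height of the protrusion above the
shaft surface) straddle the 700 nm filter from both sides — stubby spines
all below, mushroom spines all above — so the length filter is testable
in both directions. Synapses are Poisson-scattered per compartment
(outgoing on the axon, shaft synapses on dendrites, one head synapse per
spine with probability 0.9, a handful on the soma); spine-head synapse
size is coupled multiplicatively to head volume so the positive
size–volume correlation is a recoverable planted effect.

Welds are built by **interpenetration, never boolean union**: a child
tube starts on its parent's axis, a spine neck starts half a shaft-radius
under the surface, and injected merge errors (axon-on-axon crossings,
axon-on-dendrite orphans, soma bridges, double-back kinks at ≈ 165°,
width jumps of ≥ 3×) simply overlap the host. Face-level ground truth
therefore stays exact; the price is that face connectivity alone does not
join welded parts, which the skeletonizer compensates for (below).

A single integer seed drives each generator; sub-streams (geometry,
spines, synapses, error injection) are derived by fixed offsets, so
outputs are bit-identical for a fixed seed and adding spines never
perturbs the skeleton.

What the generator does **not** emulate: EM segmentation noise, mesh
holes and non-manifold artifacts, boutons and varicosities on axons,
myelin, co-linear merge errors (a stated limitation of the
strip-downstream paradigm), or realistic neuropil crowding. Passing the
synthetic benchmark shows the pipeline's logic and bookkeeping are
correct at realistic geometric scales; it does not by itself establish
performance on raw EM reconstructions.

## Preprocessing

**Cleaning** merges vertices within 1 nm and drops degenerate faces;
largest-component selection is off by default because orphan fragments
are legitimate inputs.

**Soma detection** is an inside-sphere erosion: for each sampled surface
vertex and a grid of offsets t (1–3.6 × the 2.5 µm minimum radius), the
ball of radius t centred t inward along the normal "fits" when no vertex
comes closer than 0.55 t **and** the surrounding surface is directionally
balanced (the mean unit direction to vertices within 1.3 t has norm
≤ 0.45). The offset at which a sample fits approximates the local ball
radius, so candidate centres cluster at soma centres. Candidates are
accepted when the submesh within 1.15 R is sphere-like
(`(36π V²/A³)^{1/3} ≥ 0.7` on its convex hull) and actually covers its
sphere (submesh area ≥ 0.75 × hull area — this rejects loose clouds of
passing neurites whose hull is round). Detections are ordered by volume;
an empty list is a valid outcome.

**Component flags**: no soma → `fragment`; a soma-scale body with no
emanating processes (bounding diagonal under 6 × the detected ball
radius) → `glia_like`; otherwise `neuron`. Interior-thickness criteria
were rejected here: interpenetrating construction leaves buried surface
that corrupts punch-through tests, whereas spatial reach is robust.

**Skeletonization** is a geodesic wavefront: vertices are binned by
geodesic distance from the soma surface (or from an extremal tip cap when
there is no soma) in 1 µm shells; connected clusters within a shell
become candidate nodes; cluster adjacency gives candidate edges. Three
corrections matter in practice:

* *bridging* — vertex pairs of different face-connected components within
  2.5 µm are linked, standing in for the weld collars of interpenetrating
  parts;
* *micro-component exclusion* — components with a bounding diagonal under
  6 µm (spine heads and necks) carry no centreline information and are
  left out of the wavefront; their faces re-attach through correspondence;
* *rung contraction and shortest-path tree* — a slanted wavefront splits
  one tube cross-section into arcs in adjacent shells, braiding the
  cluster graph into parallel strands. Rung edges are at most a tube
  diameter long, well under the along-axis spacing, so edges shorter than
  min(1.6 × step, 0.75 × the median candidate-edge length) are contracted
  before the shortest-path tree from the root is extracted.

Terminal twigs shorter than 8 µm are pruned (real branches in these
morphologies are ≥ 15 µm; spine stubs and cap artifacts are shorter), a
Lloyd pass recentres each node on the centroid of its nearest surface
vertices, and light Laplacian smoothing finishes. Somas collapse to a
single high-degree node at their centroid. On the benchmark morphologies
the skeleton recovers generator skeletal length to within ~5% once
soma-interior stem sections are discounted.

**Correspondence and width.** Every face is assigned to its nearest
skeleton edge via dense (250 nm) edge sampling; the local width at a
skeleton point is **2 × the median perpendicular distance** from the
centroids of macro-component faces assigned to its incident edges. The
median plus the micro-component exclusion make the estimate robust to
spines; a 500 nm cylinder measures 1,000 nm within a few percent. Faces
of one micro-component are reassigned atomically to the majority edge so
a spine never straddles two branches.

## Decomposition

The skeleton is cut at every degree-≥3 point, at the soma surface
(branches begin where the skeleton exits the soma sphere; the interior
accrues to the root, preserving total length to the nanometre), and at
sharp geometric discontinuities inside otherwise non-branching runs
(direction reversals > 100° over a 2-sample window; width steps > 600 nm
and > 1.5×). The discontinuity cuts exist because collinear welds —
double-backs and width jumps at branch tips — otherwise hide inside a
single node where node-level rules cannot see them. Residual cycles are
broken by removing the cycle edge farthest (graph distance) from the
root, each removal logged. Synapses attach to the branch with the nearest
skeleton point (soma if nearest the soma); a synapse farther than
2 × local width + 3.5 µm (the maximal spine reach) from the skeleton is
flagged invalid — the pure 2×-width rule would wrongly reject every
spine-head synapse.

**Multi-soma splitting** cuts the tree path between each pair of soma
nodes at the most suspicious edge: a weighted sum (0.5/0.3/0.2,
config-exposed) of the contact width discontinuity (median width a few
samples past the junction minus just before, normalized), the contact
branching angle, and the outgoing-synapse-fraction mismatch of the two
sides. Contact windows deliberately skip the junction sample, whose width
blends both tubes. The far side is re-rooted at its own soma with branch
polylines flipped as needed.

## Spines

Faces farther from the skeleton than 1.4 × local radius are protruding;
connected patches of ≥ 20 faces (at generator resolution) are spine
candidates. Patches that are one protrusion in two pieces — a head sphere
interpenetrating its neck — are merged when their outward rays agree
within 15°, one patch lies within 350 nm laterally of the other's axis,
and they come within 450 nm; the lateral-offset condition keeps adjacent
spines at the same azimuth separate. Spine skeletal length is the maximal
height of a face centroid above the shaft surface (distance to skeleton
minus local radius), which matches hemispheric bumps exactly and
neck + head heights for mushrooms. The head/neck split looks for a local
minimum of the 80th-percentile radial width profile along the spine axis
that drops below 0.6 × the maximal distal width; absent that, the whole
spine is head ("no neck" is a valid outcome, and is the expected outcome
for stubby spines). Head volume is the divergence-theorem volume of the
head patch closed by an implicit fan to the cut point — exact for closed
patches, within a few percent for spherical heads. On 20 seeded spiny
neurons the pooled precision and recall for spines longer than 700 nm are
both above 0.90 (the filter is strict: length > 700 nm).

## Proofreading

Rules run in a configurable order (default: axon-on-dendrite →
axon-degree → double-back(axon) → double-back(dendrite) →
width-jump(dendrite)); after each rule the flagged nodes and their entire
descendant closures are stripped, their synapses invalidated, and an edit
record stored (rule, parameter snapshot, cut location, removed nodes,
synapses and skeletal length). Stripping only removes data; nothing is
extended or reattached. Default thresholds — 120° double-back angle,
500 nm width jump (measured on contact windows), 3 children maximum at an
axonal branch point, 35° crossover angle, 0.2 spines/µm and 0.75 outgoing
fraction for axon-like subtrees — are engineering choices exposed in the
config. Because rules only remove, adding rules can only reduce false
positives and recall (monotonicity) and a second pass of the same stack
makes no further edits (idempotence); both are asserted in the tests.

## Cell typing and compartments

The E/I model is an unpenalized two-feature logistic regression on
dendritic spine density and shaft-synapse density (per µm). The fit is
convex, hence deterministic; with n = 2,000 samples from a known model
the weights recover within 15%. Axon identification scores each stem by
outgoing-synapse fraction (floor 0.5 and ≥ 2 outgoing synapses), spine
poverty and thinness; ties resolve to the lowest stem id. Compartments:
AIS = axon branches starting within 50 µm of the soma along the skeletal
walk (a default, not a measured constant); for excitatory cells the
widest stem within 45° of the pia direction is the apical trunk (side
branches oblique), the rest basal; inhibitory dendrites are all basal.

## Proximities and motifs

The axon skeleton is resampled at 500 nm; for each sample the nearest
dendritic (or soma-surface) sample of the partner is found with a k-d
tree. Contiguous runs within the 5 µm radius merge into one proximity
event; two events are distinct only when separated by more than 10 µm
along the axon (the along-axon gap is our operationalization; event
boundaries are accurate to ~step/2). Each event records its minimum
distance, closest-approach points, presyn/postsyn skeletal walks and the
postsynaptic compartment; synapses link to the nearest event of their
pair within the link radius. The conversion rate is the fraction of
events with ≥ 1 synapse (undefined for zero events). Stratified tables
support pre/post class, post compartment, walk bins and a radius sweep
that re-thresholds stored minimum distances without recomputation.

The connectivity graph has an edge pre→post when ≥ `min_synapses` valid
synapses connect the pair (autapses excluded by default; weights retain
synapse counts, the census uses the simple digraph). The triad census
counts the 16 directed three-node classes plus a coarsening by edge
count. Null models: degree-preserving directed double-edge swaps (10×|E|
attempted swaps between samples), uniform edge placement among proximity
edges, and uniform rewiring; 250 samples by default. Enrichment reports
per-class z-scores and fold ratios, with zero-variance classes listed
separately rather than scored.

## Problem sizes

The bundled benchmarks run desk-scale morphologies: 3 dendritic stems at
one branch level plus apical and axon (≈ 250–350 µm of cable, ~10⁵ mesh
faces at 10 segments/ring, ~150 spines). These sizes were chosen as the
smallest at which every geometric regime of the method is present —
multi-scale radii (0.1–5 µm), junctions, spines on both sides of the
length filter, and welds of all five error types. The statistical
benchmarks use the sample sizes of their definitions: 20 seeds for the
spine and proofreading suites, 250 null-model samples, n = 2,000 for
parameter recovery.

## Known limitations

* Skeleton node spacing (~1 µm) bounds the localization of cuts and
  branch points; cut locations are accurate to a few µm, not nm.
* Spines attached within the soma-exit clip region are absorbed into the
  soma and missed (rare; visible as a ~1–2% recall floor).
* Very thin distal branches (< 300 nm radius) show more spine-detection
  noise; the benchmark morphology keeps dendritic radii ≥ 300 nm.
* Orphan axons that graze several host branches can be split among them
  and escape the axon-on-dendrite rule; the width-jump rule usually
  catches these (observed in 1 of 20 benchmark scenes).
* The proximity event merger treats the along-axon gap in walk distance,
  which over-merges when an axon loops back within `min_gap` of itself.
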