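# Methods

`ermdquant` implements three quantitative analyses around ER-associated
mitochondrial division (ERMD) in budding yeast, exercised entirely on
synthetic 3D organelle scenes with recorded ground truth: a division–focus
association statistic with geometric random-association nulls, electron-
tomogram-style ER–mitochondria contact-surface quantification on triangle
meshes, and censored resolution-time kinetics from tip tracks.

## Division–focus association and its nulls

A division event at position x is **linked** to a focus (an ERMES- or
nucleoid-like punctum) when some focus center c satisfies |x − c| < r_link.
The linkage radius defaults to 300 nm = 1.5 × the mean focus radius
r_focus = 205 nm. The observed statistic is the linked fraction
p̂ = n_linked / n.

Under spatially random division placement, the chance of linkage equals the
fraction of the mitochondrial surface lying within r_link of a focus
center. Two estimates are provided:

* **Analytic disk dilation.** If foci are disks of radius r_focus covering a
  fraction ρ of the surface (the per-plane thresholded-area ratio; 0.045 by
  default), each linkage footprint dilates the disk to radius r_link, so

      p_null = ρ · (r_link / r_focus)²,  capped at 1.

  With the defaults, 0.045 × (300/205)² = 0.0964 ≈ 10%. The derivation is
  exact when the dilated footprints are disjoint and the surface is locally
  flat at the footprint scale.

* **Monte-Carlo null.** Uniform points on the actual surface (a triangle
  mesh, or the idealized periodic plane), scored by the same linkage rule.
  This makes no flatness or disjointness assumption. On tubular surfaces
  with radius comparable to r_link the Euclidean linkage ball wraps around
  the tube, so the Monte-Carlo null sits *above* the flat-disk value (we
  observe ≈0.14 vs 0.094 on 200 nm-radius tubes at 4.5% coverage); the
  analytic null is therefore conservative for enrichment claims on curved
  geometry.

Enrichment is tested with the one-sided exact binomial tail
P(X ≥ n_linked | n, p_null) — exact rather than a normal approximation
because realistic event counts are tens, not thousands.

The per-plane area ratio is the mean over focal planes of
(focus pixel area / mitochondrial pixel area), planes without mitochondrial
signal skipped — a plane mean, not a pooled-pixel ratio, matching how
per-plane thresholded-particle measurements are averaged.

Ties (two foci equidistant within floating-point tolerance) break to the
lowest focus index. Events with several foci in range link to the nearest.

## Contact-surface quantification

A mitochondrial face is **in contact** with the ER when its sample point
lies within the contact cutoff (30 nm) of the ER surface and the segment
from the sample point to its nearest ER point does not pass within the
ribosome exclusion radius (12.5 nm, i.e. half a ~25 nm particle) of any
ribosome center. Contact faces are segmented into connected patches under
edge adjacency (vertex-only bridges do not merge patches); patches below
`min_patch_faces` (default 3) are dropped as discretization speckle.

Numerical choices that matter:

* **Face flagging uses the face centroid**, not the minimum over centroid
  plus vertices. Centroid sampling counts a boundary-straddling face iff
  its centroid is inside the true contact region, making the flagged area
  an unbiased estimator that converges to analytic values at practical
  refinement (a spherical-cap test reaches <0.5% error at ~5 nm edges). A
  vertex-inclusive minimum (`samples="all"`, available as an option) counts
  every straddling face fully and overestimates by roughly one boundary row
  of faces — with 10 nm edges on a 100 nm-wide band that is a ~10% bias,
  decaying only linearly in edge length.
* Point-to-mesh distances are exact (two-stage KD-tree candidate search
  plus exact point-to-triangle evaluation) within the zone that can affect
  flagging; provably distant faces get a single-triangle upper bound whose
  error is below the largest face extent.
* Patch-to-patch distances are vertex-sampled minima, matching the mesh
  resolution. Note min-distances between *sets* do not obey the plain
  triangle inequality; only the relaxed form d(A,B) ≤ d(A,C) + diam(C) +
  d(C,B) holds.
* Meshes need not be watertight; tomogram-style models are open at section
  boundaries and boundary faces count fully.
* Units are nanometers internally; µm² appears only in reports.

Diameter profiles are taken along a centerline: at each arc-length sample,
diameter = 2 × median perpendicular distance from the axis point to mesh
vertices in the cross-sectional slab (half-width = half the sampling step).
Samples with fewer than 4 slab vertices are invalid (NaN), not fatal.
Constrictions are local minima below 75% of the median flanking diameter
(±300 nm window, the minimum itself excluded), and are associated with the
nearest contact patch whose surface comes within 300 nm.

Because "shortest distance between pairs of contacts" is ambiguous between
all pairs and nearest neighbours, the summary reports the full pairwise
matrix and the nearest-neighbour minima.

## Resolution-time kinetics

A tip track records the two nascent tips flanking a constriction at a fixed
frame interval (15 s) over a capture window (210 s). The track **resolves**
at the first frame at/after constriction onset where the inter-tip distance
exceeds a separation threshold and stays above it for a persistence window;
the resolution time is (frame − onset) × interval. The field describes
"tips moving independently" without a numeric rule; we operationalize it as
**500 nm for ≥2 consecutive frames** (both knobs exposed). A qualifying run
starting exactly at onset would give time 0; that boundary is rejected, so
resolved times are positive frame multiples. Tracks that never qualify are
right-censored at the capture duration ("never"); a track resolving on the
final frame counts as resolved. Whether the clock starts at constriction
onset or at the first frame of ER wrap is not observable in the synthetic
tracks; we use onset and note the alternative for real-data users.

Default profile bins are [0,15], (15,60], (60,210] s plus "never",
mirroring the wild-type expectation that constrictions resolve within
15–60 s while the mutant-like phenotype persists through capture. Group
contrasts reduce each track to resolved-vs-never and use Fisher's exact
test with a Newcombe score interval on the resolved-fraction difference;
with censoring, the category counts are the only quantity comparable
without a parametric survival model.

## The synthetic scene generator

The generator defines the study conditions; every downstream estimate has a
stored ground-truth value in `scene.truth`.

* **Mitochondrial network**: capped-cylinder tubes (radius 200 nm
  wild-type-like; 350 nm emulates the swollen mutant morphology — package
  defaults for a realistic yeast tubule, not measured values) swept along
  smoothed correlated random walks inside the extent, or straight lanes for
  tomogram-style scenes. Swept areas match the analytic cylinder sum to a
  few percent after kink smoothing.
* **Foci**: non-overlapping disk centers on the surface (minimum separation
  one diameter), added until the disk-footprint coverage n·πr²/A reaches
  the 4.5% target within ±0.2 pp. Coverage is defined against total
  surface area, which on a flat test plane coincides with the projected
  ratio the imaging pipeline measures.
* **Division events**: with probability p placed uniformly within 300 nm of
  a random focus, otherwise uniformly at >300 nm from every focus — so the
  linkage operation recovers the generating labels exactly, and p̂ differs
  from p only by binomial sampling. Nucleoids likewise, at probability
  0.85. Because associated events cluster at shared foci, a nucleoid placed
  for one event can sit within 300 nm of a neighbouring event; observed
  nucleoid association therefore slightly exceeds the generating
  probability on dense scenes.
* **ER**: tubes of radius 100 nm (the literature gives no ER dimensions;
  value chosen for realism and recorded in config). Wraps are torus arcs
  encircling a locally straight tube at a prescribed membrane gap (<30 nm
  at wraps; free tubes keep >50 nm clearance). ER tubes get spherical end
  caps, making the surface exactly the offset surface of the axis arc, so
  the ground-truth contact band — {surface points with distance-to-arc <
  r_er + cutoff} — is computed by closed-form arc distance integrated on a
  2 nm quadrature grid, independent of the mesh pipeline under test. Tube
  meshing is locally refined (4 nm rings) around wrap bands so the band
  edge is resolved; without refinement the band edge can fall between
  centroid rows and bias a single measurement by up to one row (~15%).
* **Ribosomes**: uniform Poisson points (default 2000/µm³ — below crowded
  cytosol, chosen to keep synthetic volumes light while exercising the
  exclusion rule) outside organelle interiors.
* **Tip tracks**: a resolution time is drawn from a configurable family
  (lognormal median 30 s, σ=0.35 by default, putting most mass in the
  15–60 s window; point-mass/gamma/uniform available) or censored with a
  configurable probability; tips sit on a common axis with pre-separation
  distances in 150–400 nm and post-separation distances >700 nm, so the
  separation rule fires exactly at the first frame ≥ the drawn time.
* **Label stacks**: anisotropic binary voxelizations (80 nm lateral, 400 nm
  axial; voxel centers at (i+0.5)×pitch, (z,y,x) order) of the tube volume,
  with foci rendered as dilated surface disks intersected with the
  mitochondrial volume — mirroring per-plane thresholded channels.
* **Determinism**: one master seed with a named substream per component
  (tubes, foci, events, ER, ribosomes, tracks, nucleoids), so adding a
  component never perturbs the others; identical configs reproduce scenes,
  tracks and stacks byte-identically.

What the generator does **not** emulate: point-spread functions and photon
noise, deconvolution artefacts, membrane curvature beyond circular cross-
sections, cristae, tube self-avoidance, fusion/motility dynamics, and
biological coupling between contacts and constrictions beyond what is
explicitly constructed. Passing tests demonstrate that the estimators
recover known geometric and statistical ground truth under these idealized
conditions — not that they are robust to segmentation error or imaging
artefacts in real data.

## Problem sizes

Test and analysis scenes use networks of 2–8 tubes (≈3–34 µm² of surface,
~20–40 k faces per refined tomogram-style tube), 500 events × 20 seeds for
association recovery, 100,000 events for the Monte-Carlo/analytic
comparison, and 29-track cohorts for kinetics — sizes chosen so the full
suite exercises every contract at interactive runtimes.

## Known limitations

* Coverage is defined on total surface area; for strongly curved surfaces
  the imaging-style projected ratio differs (the analytic null should then
  be fed the measured per-plane ratio, as the pipeline does).
* Contact ground truth assumes local straightness of the wrapped tube;
  wraps are only generated on straight segments.
* The exact-geometry patch areas count whole faces; per-patch areas
  quantize at the face scale even though totals are unbiased.
* `compare_groups` discards resolved-time information; a survival model is
  out of scope.
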