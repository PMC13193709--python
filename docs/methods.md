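# Methods

This note documents the models and procedures implemented in `phagotrack`,
the choices made where the design was open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Scope and data model

The pipeline operates on single-z, two-channel (myeloid, tumor) time-lapse
images with pixel size (μm/px) and frame interval (s) metadata; frame
intervals are expected in the 50–60 s range typical of intravital two-photon
imaging (default 55 s). Selection of the analysis z-slice from a 4D
acquisition is left to the user; movies and masks are single-z by contract.

## Segmentation

The baseline segmenter is deliberately parameter-light and deterministic:
Otsu threshold (or a fixed value), morphological opening with a radius-1
disk, hole filling, connected-component labeling, and removal of components
below `min_area_px2` (default 10 px²). It is a baseline for synthetic and
well-contrasted data; for dense tissue, externally produced label masks
(e.g. from a learned model) can be imported via `import_masks`, which
validates shape and dtype, and flow through the identical downstream path.
Coordinates are 0-based (row=y, col=x) with pixel centers at integers. A
constant frame yields an empty mask, not an error.

## Tracking

Linking is the standard nearest-neighbor particle-linking scheme: per
consecutive frame pair, a one-to-one assignment between active track ends
and new detections minimizing total squared displacement, computed with the
Hungarian algorithm on a gated cost matrix. Pairs farther than
`max_disp_px_per_frame` are forbidden; the penalty encoding guarantees the
solver first maximizes the number of gated matches, then minimizes cost
(verified against exhaustive enumeration in the tests). Unmatched
detections seed new tracks; a track unmatched for more than `memory_frames`
(default 0) is closed. The gate has no universal default — it should be set
from the fastest plausible per-frame step; the tests derive it as
(max population speed + 4 sd) × frame interval + 2 px of centroid jitter.

Track length is counted as the number of detections, and the minimum-length
filter is inclusive: with the default of 5, a 5-detection track is retained
("minimum" denotes the smallest allowed value). Gap frames bridged by
memory do not count toward length. Equal-cost assignment ties are resolved
by the (deterministic) Hungarian implementation; only cost-optimality, not
a specific tie order, is guaranteed.

## Track features

Each track maps to a named 15-vector: five morphology track-averages
(mean/sd area in μm², mean eccentricity, mean solidity, mean equivalent
diameter in μm) and ten motility terms (duration in frames; path length;
net displacement; straightness = net/path, 0 for a closed path; mean, max
and sd of per-step speed in μm/min, where a step spanning a gap uses the
elapsed time; mean turning angle between consecutive nonzero steps, degrees
in [0, 180], 0 when fewer than two such steps; arrest coefficient =
fraction of steps slower than `arrest_speed_um_per_min`; displacement rate
= net displacement / track duration). A single-detection track has all
motility entries 0 and morphology from its one detection, keeping the
vector finite and the layout fixed.

The arrest cutoff defaults to 2 μm/min — a conventional boundary between
arrested and motile myeloid cells in tissue — and is configurable; it is a
physical (μm/min) threshold, so it scales with pixel calibration rather
than being invariant to it.

## Classification

The annotation-balancing rule sorts tracks by mean area and alternates
between the largest and smallest remaining tracks (ties by ascending
track_id; for odd counts the median-area track comes last), which front-
loads both ends of the size distribution and yields roughly class-balanced
annotations. The split is stratified by class and seeded:
round(0.8·n_class) tracks per class to training. The classifier is a
linear hinge-loss max-margin model (C = 1.0) on features standardized with
training-split statistics only; a zero-variance feature receives scale 1
and thus zero influence. Linear was chosen over kernels for determinism and
interpretability of the 15 weights. Predictions carry signed margins so
low-confidence tracks can be flagged for manual review; no automatic
post-hoc correction is attempted.

## Contact quantification

Occupancy map: per frame, threshold (Otsu default or fixed), closing then
opening with a radius-2 disk, hole filling. Closing-before-opening bridges
fragmented tumor signal before removing speckle; both the radius and the
order are config-exposed since the exact morphology of real tumor channels
varies. Global occupancy is the mean over frames of the per-frame tumor
area fraction (equal to the pooled fraction for constant frame size).

Overlap fraction uses a Euclidean-disk dilation of radius 3 px (clipped at
borders); a disk was chosen for rotation invariance, with a square element
available in config. The contact threshold is strict (> 0.10): a frame at
exactly 10% overlap is not a contact. Enrichment is reported per track
(mean overlap over the track's frames ÷ global occupancy). When global
occupancy is 0 the ratio is undefined: `contact_enrichment` raises, and
`contact_series` records NaN (never a silent 0) unless the track's overlap
is identically 0, in which case 0 is returned as the unambiguous limit.
Contact metrics are intended for macrophage-classified tracks (or any
user-supplied class filter).

Group comparison: two-sided Wilcoxon rank-sum. Exact enumeration when both
groups have ≤ 20 observations and no ties; otherwise the tie-corrected
normal approximation with continuity correction. Two groups whose pooled
values are all identical return p = 1.

## Histology rules

Double-positive calling is centroid-to-centroid Euclidean distance,
inclusive at the 5.0 μm boundary. Centroid (not surface) distance is this
package's documented contract; surface-to-surface distances would require
segmented cell outlines that point tables do not carry. Point-in-polygon
counts boundary points as inside (shapely `covers`). Masked object counting
uses the object's centroid pixel by default ("inside" semantics,
unambiguous for border-straddling objects), with an any-pixel mode in
config. Per-layer densities are reported per mm² of ROI area.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* **Two myeloid populations** with Gaussian areas and speeds. Defaults:
  macrophages 120 ± 15 μm², 1.0 ± 0.4 μm/min, low directional persistence;
  neutrophils/monocytes 40 ± 8 μm², 8 ± 2 μm/min, higher persistence —
  values typical of skin intravital imaging, where macrophages are large
  and sessile while neutrophils patrol rapidly.
* **Persistent random walks**: each step rotates the previous heading by a
  wrapped-normal angle with sd π·(1 − straightness_bias) and draws a fresh
  speed. Cell centers reflect off the borders at one cell-radius margin,
  and a step that would bring two cell boundaries within
  `min_separation_um` (default 2 μm, steric exclusion) is retried and
  otherwise skipped, so rendered cells never overlap and the ground truth
  is unambiguous.
* **Rendering**: cells are filled ellipses of constant per-cell area with
  axis ratio drawn in [1, 2]; the tumor channel is a sum of disk blobs;
  additive Gaussian pixel noise (default sd 0.02 against cell intensity 1).
  Ground-truth centroids/areas are measured from the rendered pixels, so
  the truth table is consistent with the masks by construction.
* **Histology patterns**: B-marker points uniform in the field; exactly
  round(coupling_fraction·n_A) A points uniform within `coupling_dist_um`
  of a random B point, the rest uniform.

What the generator does **not** emulate: z-drift and stage drift,
photobleaching, uneven illumination, touching/overlapping cells, cell
division or death, shape dynamics (each cell keeps one ellipse), and the
dense, low-contrast environments that motivated learned segmentation.
Passing tests therefore validate the *algorithms* (linking optimality,
feature arithmetic, enrichment normalization, boundary conventions), not
segmentation robustness on real tissue.

## Numerical and testing choices

Determinism everywhere: all generators and the classifier are seeded; the
same spec + seed is bit-identical. The enrichment null calibration places
each of 500 simulated tracks on its own freshly drawn occupancy field
(exact coverage fraction by pixel permutation), making tracks independent
so the 3-standard-error acceptance band is valid; sharing a single field
realization across tracks would correlate them and invalidate the naive
standard error. Problem sizes in the test suite (200² px movies, 20 frames,
24–30 cells; 500-track calibrations; 2,000 null simulations for the type-I
check) were chosen so the whole suite completes in well under a minute
while keeping Monte-Carlo bands tight.

## Known limitations

* The baseline segmenter under-performs on dense or low-contrast data;
  import masks from a dedicated model in that regime.
* Linking handles neither merges/splits nor 3D.
* The 15-feature set is one standard motility-phenotyping choice; the
  classifier interface accepts any fixed named feature layout, but the
  serialized default is this set.
* Enrichment assumes the occupancy map is a faithful tumor indicator;
  systematic thresholding bias propagates directly into ρ and hence E.
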