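# phagotrack

Quantification of macrophage–tumor interactions in intravital two-photon
time-lapse imaging.

Tissue-resident macrophages (e.g. CD169⁺ skin macrophages) contact and
ingest tumor cells within days of tumor inoculation. Measuring that
interaction in live-tissue movies is hard for two reasons: (i) myeloid cells
must first be told apart — neutrophils/monocytes are usually smaller and
faster than macrophages, but size and speed alone misclassify static
neutrophils and motile macrophages — and (ii) individual tumor cells are
hard to segment reliably, so naive contact counting is noisy and depends on
how much of the field the tumor happens to cover.

`phagotrack` implements a pipeline that addresses both:

1. **Track-based cell discrimination.** Cells are segmented per frame,
   linked into trajectories (minimum-total-squared-displacement assignment
   per frame pair), and tracks shorter than 5 frames are dropped. Each track
   is summarized by a **15-dimensional feature vector** (morphology
   track-averages + motility descriptors such as path length, straightness,
   speeds, turning angle, arrest coefficient), and a linear max-margin
   (hinge-loss SVM) classifier separates macrophages from
   neutrophils/monocytes. An annotation-balancing rule (alternate between
   the largest- and smallest-area remaining tracks) and a stratified, seeded
   80:20 train/validation split support the labeling workflow.

2. **Occupancy-normalized contact quantification.** The tumor channel is
   reduced to a per-frame binary *occupancy map* O_t (threshold +
   morphology). For a macrophage with mask M_t, the mask is dilated by 3 px
   and the *overlap fraction* is

       w_t = |dilate(M_t) ∩ O_t| / |dilate(M_t)|.

   A frame is a *contact event* when w_t > 0.10 (strict), and *total contact
   time* is the number of contact frames × frame interval. The headline
   statistic is per-track **contact enrichment**

       E = mean_t(w_t) / ρ,   ρ = global tumor occupancy
           (mean fraction of image area occupied by tumor signal),

   so E > 1 means the cell preferentially sits on tumor-occupied regions
   relative to their spatial availability, comparable across movies with
   different tumor coverage. Groups are compared with the two-sided Wilcoxon
   rank-sum test.

3. **Histology spatial rules.** For still images: double-positive calling
   by proximity (an IBA1⁺ cell within ≤5.0 μm of a CD169⁺ cell, boundary
   inclusive), inside/outside-region partitioning against a polygon, and
   counting labeled objects restricted to a binary region mask.

A seeded synthetic-data module generates two-channel movies (two myeloid
populations on persistent random walks + a clustered tumor channel) with
exact ground truth, and histology-style point patterns with controllable
marker coupling, so the whole pipeline is testable without any raw data.

## Worked example

```python
import numpy as np, pandas as pd
import phagotrack as pt

spec = pt.MovieSpec(
    n_frames=20, height_px=200, width_px=200, seed=1, noise_sd=0.0,
    tumor_blobs=[((100.0, 100.0), 45.0, 1.0)],
)
movie, truth = pt.generate_movie(spec)
masks = pt.segment_movie(movie.channel("myeloid"))
dets = {t: pt.regionprops(masks[t], frame=t) for t in range(spec.n_frames)}
tracks = pt.filter_tracks(pt.link(dets, pt.LinkConfig(max_disp_px_per_frame=15)))
print(f"{len(tracks)} tracks recovered ({len(truth.classes)} cells simulated)")

# label recovered tracks from ground truth, train the classifier
def true_class(track):
    d = track.detections[0]
    rows = truth.tracks[truth.tracks["frame"] == d.frame]
    dist = np.hypot(rows["y_px"] - d.centroid_yx_px[0],
                    rows["x_px"] - d.centroid_yx_px[1])
    return truth.classes[int(rows.iloc[int(np.argmin(dist))]["track_id"])]

feats = pt.features_table(tracks, spec.pixel_size_um, spec.frame_interval_s)
labels = pd.DataFrame({"track_id": [t.track_id for t in tracks],
                       "class": [true_class(t) for t in tracks]})
train, val = pt.split(labels, 0.8, seed=1)
tr = feats.merge(train, on="track_id"); va = feats.merge(val, on="track_id")
model = pt.TrackClassifier(seed=1).fit(tr, tr["class"])
print("validation accuracy:", pt.evaluate(model, va, va["class"])["accuracy"])

# occupancy-normalized contact quantification for predicted macrophages
cfg = pt.ContactConfig()  # dilation 3 px, contact threshold 0.10
occ = pt.build_occupancy(movie.channel("tumor"), cfg)
print(f"global tumor occupancy: {occ.global_occupancy:.3f}")
pred = model.predict(feats)
macs = [t for t, c in zip(tracks, pred["class"]) if c == pt.MACROPHAGE]
recs = [pt.contact_series(t, masks, occ, spec.frame_interval_s, cfg) for t in macs]
enr = [r.enrichment for r in recs]
print(f"mean enrichment over {len(enr)} macrophage tracks: {np.mean(enr):.2f}")
```

Output:

```
30 tracks recovered (30 cells simulated)
validation accuracy: 1.0
global tumor occupancy: 0.159
mean enrichment over 15 macrophage tracks: 1.76
```

All 30 simulated cells come back as complete tracks; the classifier
separates the two populations perfectly on held-out tracks; the tumor disk
covers 15.9% of the field (π·45²/200² = 0.159); and since macrophages wander
into the central tumor disk and linger, their mean enrichment exceeds 1
(uniformly placed cells would average 1.0).

The same pipeline is available as a CLI:
`phagotrack simulate|segment|track|features|classify|contact|spatial --help`.

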