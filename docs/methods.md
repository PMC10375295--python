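# Methods

`siliqueseg` counts the seed pods (siliques) of mature rapeseed plants
from 3D point clouds, with supporting stages that take the data all the
way from a hand-held video to a per-plant count. This note documents the
models and procedures, the parameters that matter, what the synthetic
data does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Pipeline overview

1. **Keyframe selection** — pick a sharp, evenly-overlapping subset of
   video frames for reconstruction.
2. **Reconstruction (external)** — structure-from-motion is delegated to
   an external tool behind a subprocess adapter; the package never
   implements SfM itself.
3. **Background removal** — passthrough filter (keep points whose
   coordinate on one axis lies in a closed interval).
4. **Downsampling** — farthest-point (default) or random sampling to the
   network's input size.
5. **Semantic segmentation** — an EdgeConv graph network labels each
   point stem (0) or silique (1); a non-learned geometric baseline is
   available for runs without training.
6. **Sparse-dense mapping** — silique labels are transferred back to the
   full-resolution cloud by radius search around silique-labeled sparse
   points.
7. **Counting** — the dense canopy is clustered and mined for straight
   rods by iterative RANSAC line fitting; one accepted line = one
   silique.

## Keyframe selection

Sharpness is the variance of the Laplacian (4-neighbour template
`[[0,1,0],[1,-4,1],[0,1,0]]`, reflect borders) of the bilateral-filtered
grayscale image. The bilateral filter (window 9, sigma_color 75/255,
sigma_spatial 75) removes sensor noise that would otherwise masquerade
as high-frequency detail; grayscale conversion uses BT.601 luma weights.
A frame is "blurred" when its score falls below `blur_threshold`; by
default that threshold is sequence-relative (the 10th percentile of the
sequence's scores), because absolute Laplacian variance depends on scene
texture.

Similarity between two frames is `100 * MatchNum / Matches`: ORB
keypoints (scikit-image, 400 per frame) matched 2-nearest-neighbour by
Hamming distance, with Lowe's ratio test (`d1 <= 0.7 * d2`) deciding
which candidate matches survive. `Matches` counts the candidate pairs
before the ratio test. The detector is pluggable; ORB is the default
binary-descriptor choice.

The selection loop starts at the first non-blurred frame and tests the
frame `interval_k` ahead (skipping blurred frames): similarity within
`[s1, s2]` accepts; above `s2` (too redundant) advances by `step_i`;
below `s1` (too little overlap) retreats by `step_i`. Similarity is
always evaluated against the previous *accepted* keyframe. Because the
raw loop has no termination guarantee, an oscillation guard skips one
coarse interval past the furthest frame examined whenever the fine
adjustment revisits an index; the scan position then increases strictly,
so selection always terminates. Defaults scale with sequence length
(`interval_k ~ n/120`, `step_i ~ interval_k/5`, `s1=25`, `s2=65`), all
overridable.

## Dataset preparation

Training clouds are expanded six-fold: each copy draws one translation
vector (components uniform in [-0.2, 0.2]) and three per-axis scale
factors (uniform in [0.65, 1.7]); points are scaled then translated
(the order is pinned and observable through `draw_transforms`). The
augmented pool splits 70/15/15 into train/validation/test with val/test
sizes rounded half-down (remainder to train; 540 clouds -> 378/81/81,
10 -> 8/1/1), and all copies of one source plant stay inside a single
partition so no plant leaks across splits.

## Segmentation network

The segmenter is a dynamic-graph EdgeConv stack. Each EdgeConv layer
builds a kNN graph (k = 20) — recomputed in feature space after every
layer — and maps each edge's feature `(x_i, x_j - x_i)` through a shared
MLP (leaky ReLU, widths {64,64}, {64,64}, {64}), max-pooling over each
point's edges. A spatial-transform branch estimates a 3x3 alignment
matrix (zero-initialized final layer with identity bias, so the network
starts at the identity). The segmentation head concatenates all EdgeConv
outputs (192 channels) with a 1024-wide global max-pooled descriptor and
maps through 256/128 to the per-point class scores. The loss is the mean
softmax cross-entropy `-log(exp(x[label]) / sum_j exp(x[j]))`, optimized
with Adam.

The network runs on a small reverse-mode autodiff written for this
package (`_autodiff.py`): float32 tensors, matmul/gather/concat/max ops
with tape-recorded backward passes. The reference training profile is
8192 points, 200 epochs, batch 20, learning rate 0.001
(`DGCNNConfig.paper_profile()`); the default desk-scale profile (1024
points, 30 epochs, batch 4) trains to >0.99 held-out point accuracy on
synthetic plants in about two minutes on one CPU. Inference on clouds
larger than the input size runs on random disjoint chunks; smaller
clouds are padded by resampling.

The geometric baseline classifier (`baseline_segment`) calls a point
silique when its pod-scale neighbourhood is linear, its height exceeds a
z-quantile, and it lies away from the central vertical axis (the
horizontal median of the lower half of the cloud). The axis-distance
feature carries most of the discrimination here: a stem whose radius is
comparable to the pod radial noise is itself rod-like at pod scale, so
linearity alone cannot separate the classes. The baseline presumes a
single dominant vertical stem and exists to exercise the downstream
stages without a training run, not to substitute for the network on real
scans.

## Sparse-dense mapping

Every dense point within `radius` (default 0.01, cloud units) of at
least one silique-labeled sparse point is retained, once (union
semantics, closed ball). Stem-labeled sparse points play no role. A
`normalize` option rescales both clouds so the dense bounding-box
diagonal is 1 before searching, for data whose units are unknown.

## Counting

The canopy cloud is split into connected components at
`cluster_tolerance` (0.02 m default; computed exactly — DBSCAN with
`min_samples=1` is the connected-components of the eps-graph — and
verified against a union-find oracle). Clusters below
`min_cluster_size` (200) are dropped. Each cluster is then mined
iteratively: fit a line, record it, remove its support, repeat until
fewer than `min_line_points` (200) points remain or no valid model is
found (a failed fit is discarded without incrementing the count, per the
misidentification rule).

One fit proceeds as follows:

* **Hypotheses.** 1000 two-point samples; the second point is drawn from
  a pod-scale annulus (0.012–0.06 m) around the first so that, in a
  cluster holding a dozen pods, most hypotheses connect two points of the
  same pod. Hypotheses are scored against a bounded subsample (<=2500
  points) with a core-weighted soft consensus (quadratic kernel, core
  width = band/4): a line threading the dense core of one pod outranks a
  longer line grazing the flanks of two.
* **Validated refinement.** The top-ranked hypotheses are refined in
  score order and the first valid model wins. Refinement starts from a
  strict half-band support and iterates: least-squares axis (first
  principal component); a bimodal cross-section (two parallel pods
  straddling the axis) is split by 2-means and the dominant lobe kept,
  honoured only when the lobe centres are farther apart than 1.8x the
  band (lumps of one pod stay closer); a kinked or over-long support is
  cut at the axial position minimising the two-piece residual, keeping
  the larger side if it is still rod-like; inliers are re-gated at the
  full band but only within the support's axial extent (a silique is a
  finite rod — an infinite line would swallow collinear neighbours),
  only where the point's local direction agrees with the axis within
  45 degrees, and trimmed to the largest contiguous axial run (gaps
  larger than `cluster_tolerance` separate pods).
* **Validation.** A model needs >= `min_line_points` support, a
  bounding-cylinder width (twice the maximum inlier-to-axis distance on
  the refit axis) inside `[width_lo, width_hi]` (0.03–0.05 m), an axial
  extent below `max_length` (0.09 m — above the biological length range),
  and a centrally-dense residual profile (median inlier residual below
  0.6x the band; a "ghost" line threaded through the leftover fringe of
  already-removed pods is hollow and is rejected).
* **Local directions** are the principal components of ~0.02 m ball
  neighbourhoods, computed on a subsample and inherited by nearest
  assignment. A crossing pod's points sit inside a line's distance band
  near the crossing, but their local direction betrays them; this is
  what lets both members of an adhered pair be counted.

Finally, two accepted lines that are nearly parallel (<=20 degrees),
laterally coincident (offset below half the band) and axially abutting
(within the contiguity gap) are merged — sequential removal occasionally
fits the far end of one pod separately, and real collinear neighbours
keep a wider gap so they are never merged.

The defaults follow the field-measured values: inlier band 0.018 m,
width range 0.03–0.05 m, 200-point minimum. Note the internal tension
documented on `CountingParams`: a band of 0.018 m caps the measurable
width at 0.036 m, so the upper half of the width range is only reachable
for supports wider than the band; both the band and the range are
plain config fields.

Counting metrics: per plant Pr = 100*correct/true; totals are column
sums; MAPE is the mean per-plant percentage error; R^2 is the
coefficient of determination of the identity prediction
(1 - SS_res/SS_tot). On the published twelve-plant table the rows sum to
1454/1425/29 although the printed total row says 1457/1425/32; the
per-plant precisions and the MAPE (1.96%) are reproducible from the rows
and are what the tests assert. R^2 from the rows is ~0.99; the source
reports 0.96 and 0.97 in different places, so R^2 is computed and
reported but not gated.

## Synthetic data

`make_plant` builds a vertical stem (noisy cylinder shell, radius
8 mm, height 1 m) carrying N straight silique segments attached along
the upper stem on a golden-angle spiral (the phyllotactic arrangement of
a raceme), each sampled with Gaussian radial noise. Defaults mimic the
scale of real scans: ~260k points per plant (2000 per silique, 20k
stem), silique length 5–8 cm, 85–196 siliques per plant supported.
Radial noise sigma is 0.006 m so that ~99% of a pod's points lie within
the counting band and the measured width lands inside 0.03–0.05 m;
non-adhered silique axes keep a pairwise clearance of at least 0.036 m
(twice the band). `adhesion_fraction` of the pods are placed crossing a
neighbour at 40–80 degrees, with the crossing at 0.55–0.85 of both
segments' lengths (pods tangle toward their distal ends; an interior
crossing at this band width would leave the host unrecoverable by any
line-consensus method). Infeasibly crowded specs raise after bounded
retries rather than silently violating clearance.

What the generator does **not** emulate: leaves, flowers and pedicel
curvature; pod curvature (real siliques bow slightly); branch stems;
reconstruction artifacts (holes, ghost points, non-uniform density);
colour. Passing counts on synthetic plants therefore demonstrate the
geometry pipeline — clustering, consensus fitting, disambiguation of
adhered and collinear pods at field-realistic densities — not
performance on real reconstructions, which additionally depends on
SfM quality and trained-network accuracy.

`make_frame_sequence` renders a blobby high-contrast texture under a
slowly drifting rotation+shift (1.2 degrees and 0.6 px per frame by
default), Gaussian-blurring chosen frames; similarity decays with lag
and blurred frames score clearly below sharp ones, which is what the
keyframe stage needs from it. It does not emulate exposure changes,
rolling shutter or parallax.

## Problem sizes used by the test suite

The acceptance tests run, on one CPU, with: counting recovery on 20
plants of 85–196 pods at 900 points per pod; mapping fidelity at the
full default scale (~260k dense, 8192 sparse); network training on the
desk profile (1024 points, 30 epochs, batch 4, 8+2 plants of ~7.5k
points). These sizes are the package's test profile; the generator's
own defaults (2000 points per pod) remain the reference conditions.

## Known limitations

* The counting stage assumes straight pods; strongly curved pods would
  be split or width-rejected.
* `min_line_points` and `min_cluster_size` are absolute counts, so the
  counting defaults presume roughly field-scale point densities
  (hundreds of points per pod); very sparse clouds need both lowered.
* The baseline segmenter assumes one dominant vertical stem.
* Determinism holds for fixed seeds on a fixed BLAS; bit-level results
  may differ across numpy/BLAS builds, though all acceptance margins are
  far wider than that.
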