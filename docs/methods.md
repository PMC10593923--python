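# Methods

`stentexpand` predicts whether a coronary stent will fail to expand fully
("under-expansion") from pre-stent intravascular OCT segmentation masks.
This note records the models, the synthetic data that stands in for patient
pullbacks, the numerical choices, and what the tests do and do not show.

## The prediction problem

A pullback is an ordered stack of cross-sectional label masks (background /
lumen / calcification) with in-plane pixel spacing and a frame spacing along
the vessel. The per-frame stent expansion index is

    SEI(f) = post-stent lumen area(f) / mean(ref_prox, ref_dist) × 100,

where the references are the largest lumen areas adjacent to the stented
segment. A stent with minimum SEI (mSEI) ≤ 80% is under-expanded (the
positive class); > 80% well-expanded. The pipeline regresses the post-stent
lumen area from pre-stent lumen and calcification features, converts the
predicted curve to SEI, extracts the minimum, and classifies.

Three analysis designs are supported:

- **frame** — 24 per-frame features (12 lumen, 12 calcification), one row
  per stented frame;
- **segmental** — a moving window of odd length L ∈ {3, 7, 15, 31, 63}
  (stride 1) summarizes each per-frame feature with 7 first-order statistics
  (min, max, mean, median, sample SD, skewness, non-excess kurtosis),
  giving 24×7 = 168 aggregated columns per full-window center, plus
  window-level lumen volume, calcification volume and calcification
  percentage; the target is the post-stent area at the center frame;
- **lesion** — one row per lesion: 16 volumetric (3D) features plus
  whole-segment aggregates of the 2D features and an optional one-hot
  calcification phenotype; target = minimum post-stent area in the segment.

Feature conventions worth stating because they are easy to get subtly
wrong: angular quantities are measured about the lumen centroid;
calcification thickness/depth are read along rays cast from that centroid
at 1° resolution (radial step 0.5 px); when a frame holds several deposits,
area and perimeter are summed, the "max"-named quantities take the per-frame
maximum, and ellipse-style descriptors come from the largest deposit.
Deposit depth is the radial gap between the lumen border and the deposit's
leading edge, so superficial sheets measure ≈ 0. At the angular tips of a
sector only the deposit's outer corner lies on a ray, which would fake a
deep leading edge; tip rays are excluded from the depth maximum (radial
extent ≥ 0.75 × median over rays, one-ray circular erosion).

Percent area stenosis uses mean(ref_prox, ref_dist) as its denominator —
the same normalization as the SEI — and analysis is restricted to the
stented segment.

## Models and validation

Min–max normalization to [0, 1] is fitted on training rows only; features
whose absolute physical magnitude matters (areas, volumes, lengths,
diameters, thickness, depth, perimeters) stay on their native scale.
Held-out values outside the training range pass through unclipped.

LASSO (internally standardized, penalty chosen by lesion-grouped CV
minimizing RMSE along the path) ranks features by absolute standardized
coefficient; ties break by earlier entry on the path. The hand-picked CLE
("calcification lesion expansion") subset is the fixed 20-column group
covering calcification angle/area/thickness/depth and lumen area/%AS
statistics plus lumen volume, calcification volume and calcification
percentage.

Model families: linear regression, Gaussian-process regression
(constant × RBF + white-noise kernel on standardized inputs, hyperparameters
by marginal likelihood with 2 seeded restarts — a single default start
occasionally collapses into the noise kernel), plus decision tree, SVR and
random forest behind the same interface. GPR training cost is cubic in
rows, so above 1500 rows the training set is thinned systematically (every
k-th row); stride-1 windows are almost entirely redundant with their
neighbours, and thinning preserves lesion coverage far better than random
subsampling of the same size.

Cross-validation is 5-fold and **lesion-grouped**: all rows of a lesion
share a fold, since neighbouring frames would otherwise leak between
training and validation. Normalization and LASSO are refit inside every
fold. Folds stratify by expansion class when per-lesion labels are
available and each class can fill every fold.

For frame and segmental modes the predicted area curve is median-filtered
over 5 frames (≈ 1 mm) before SEI extraction: per-frame prediction noise is
approximately independent while the true area profile is smooth at that
scale, and the minimum of ~100 noisy values otherwise carries a systematic
downward bias. Predictions are floored at 0.1 mm².

Classification metrics take under-expansion as the positive class; the ROC
sweeps a threshold over predicted mSEI (score = 100 − mSEI) with
trapezoid-rule AUC. The raw calcium score enters its ROC as a 5-level
ordinal score.

## The calcium-score baseline

The comparison score assigns 2 points for maximum calcium angle > 180°,
1 point for maximum thickness > 0.5 mm and 1 point for calcium length
> 5 mm (strict inequalities); total 4 predicts poor expansion. Its ML
variant trains the pipeline's lesion-mode model family on exactly those
three measurements. It regresses the actual minimum SEI rather than the
minimum area: the three calcium features carry no vessel-size information,
so an area target would force a division by an unseen reference at
evaluation time and destroy the ranking the features do support.

## Synthetic lesions

Patient data are not distributable, so the generator emulates the
structure the pipeline assumes, at two scales: the full acquisition
geometry (375 frames / 75 mm, 512×512 at 0.02 mm/px) and a reduced preset
(120 frames, 128×128 at 0.08 mm/px) used by the test suite.

Each lesion has: a conically tapering baseline lumen (proximal/distal
reference-area ratio uniform in 1.0–1.4) with a Gaussian stenosis dip
(25–55% radius loss, σ 3–8 mm); 1–3 main calcific deposits (lengths
3–15 mm — calcium in lesions referred for stenting runs long) rendered as
annular sectors with phenotype-dependent geometry, plus a Poisson(2) number
of small scattered "spotty" deposits (0.6–2.5 mm, 15–60°) that are
ubiquitous in calcified vessels and inflate lesion-wide calcium statistics
without changing the worst local burden; and a phenotype drawn from the
reported mix (nodule 13%, protrusion 23%, sheet 64%). Eruptive nodules get
an irregular (jittered) leading edge, protrusions bulge into the lumen,
sheets lie wide and thin at depth ≈ 0.

Ground-truth post-stent areas come from an explicit expansion response:

    E(f) = clamp(1 − α·g_ph·(θ̄_w(f)/360)·min(T̄_w(f)/T₀, 1), E_min, 1)
    post_area(f) = max(E(f)·A_healthy(f) + ε, 0.5·A_healthy(f)),

with θ̄_w, T̄_w the per-frame calcification angle and thickness averaged
over ±15 frames (the ±3 mm neighbourhood that matches the empirically
optimal 31-frame segment), A_healthy the dip-free tapering caliber the
stent would restore, ε ~ N(0, 0.1 mm²) registration/measurement noise, and
g_ph a phenotype burden factor (protrusion 1.3, nodule 1.1, sheet 0.85 —
protruding phenotypes resist dilation more per unit calcium, and
protrusions show the lowest mSEI). Defaults α = 0.65, T₀ = 1 mm,
E_min = 0.4 were calibrated once by closed-form simulation so that 40–60%
of lesions are under-expanded at both scales. The response is a modeling
device for generating learnable data with the right comparative structure;
it is not fitted to patient outcomes.

What the generator deliberately encodes, and why: the windowed response
makes neighbourhood-aggregated (segmental) features more informative than
single-frame ones; taper and deposit multiplicity/clutter make
location-resolved analyses more informative than whole-lesion summaries;
the phenotype factor gives the lesion-level model a recoverable gain from
the phenotype covariate. What it does **not** emulate: OCT speckle and
attenuation, segmentation errors, guidewire shadows, side branches,
eccentric lumens, pre/post registration error beyond additive area noise,
or any fitted relation between real calcium morphology and expansion.
Passing the end-to-end tests therefore demonstrates that the pipeline's
machinery recovers a signal of this documented form — not clinical
performance.

## Numerical choices

- **Perimeter**: marching-squares contour length with diagonal-step
  reweighting (factor 0.633/(√2/2)); unbiased within ~1% for digitized
  disks, ellipses and axis-aligned rectangles (45°-rotated straight edges
  remain underestimated; vessel contours are smooth).
- **Surface area**: marching cubes after a light Gaussian pre-smoothing
  (σ = 1 px in-plane, 0.5 frame longitudinally; binary fallback for thin
  structures) to remove the ~5% staircase overestimate.
- **3D connectivity**: 26-connected components define deposits; deposit
  length is the longitudinal span of the longest deposit; volume index is
  volume per unit lesion length.
- **Convex volume**: 3D hull over boundary-voxel corners (degenerate
  geometry → 0, with solidity 0).
- **Arc angle**: minimal circular interval covering the deposit's pixel
  polar angles, so wrap-around deposits measure their true small span and a
  ring measures 360°.
- **Aggregation sentinels**: constant windows return SD = skewness =
  kurtosis = 0.
- **Ties**: the mSEI location takes the smallest frame index; LASSO ranking
  ties break by earlier path entry, then column order.
- **Determinism**: every stochastic step (geometry sampling, noise, fold
  shuffling, GPR restarts) flows from explicit integer seeds; the CLI
  writes a manifest (config, seed, version, input hashes) per stage.

## Evaluation protocol on synthetic cohorts

The comparative numbers quoted by the test suite are means over three
seeded 78/32 train/held-out splits of one seeded 110-lesion cohort at the
reduced scale — single 32-lesion splits have an AUC standard error of
≈ 0.06, and split-averaged comparison mirrors how fold-averaged results
are reported for this problem. On that protocol the segmental CLE + GPR
pipeline reaches mean held-out AUC ≈ 0.93 and area-curve Pearson r ≈ 0.95,
with the orderings segmental ≥ frame ≥ lesion and
pipeline ≥ score-features-ML ≥ raw score.

## Known limitations

- Masks are trusted as ground truth; there is no artifact handling
  (guidewire shadow, side branches) and no pre/post registration.
- Phenotype is an expert label passed through, never inferred.
- The synthetic expansion response is stylized; absolute metric values on
  synthetic cohorts say nothing about patient data.
- Coarse-grid feature extraction (0.08 mm/px) quantizes thickness/depth to
  ~1–2 px; fine-scale accuracy claims hold at 0.02 mm/px.
- The 45°-edge perimeter regime and GPR beyond ~1500 training rows (thinned)
  are approximations by design.
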