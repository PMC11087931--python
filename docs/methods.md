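# Methods

`caaseg` implements and commissions an auto-contouring pipeline for the
**cardiac avoidance area (CAA)** — the radiosensitive base-of-heart region
treated as a single organ at risk in lung radiotherapy planning. The CAA is
the union of four substructures: the right atrium, the aortic valve root, and
the proximal left and right coronary arteries, the coronaries contoured at a
standard 7 mm width over their first 2 cm from the ostia. This note documents
the models, the synthetic data the package validates itself on, the numerical
choices, and what the tests do and do not demonstrate.

## Pipeline

1. **Heart localisation** (`preprocess.localize_heart`). The published
   clinical workflow relies on an external heart-localisation method that is
   not reproducible from the available description, so the package uses its
   own deterministic heuristic: the body is the largest connected component
   above −300 HU; the lungs are the two largest sub−400 HU components inside
   the hole-filled body; the heart centre is the centroid of soft tissue lying
   between the two lungs over the middle half of their shared axial range. On
   phantoms this lands within ~10 mm of the true heart centroid, which is
   ample for a 128×128×64 crop. It assumes two air-filled lungs are visible
   and fails loudly otherwise.
2. **Crop** to a fixed block (default 128×128×64 voxels) centred on the
   heart; out-of-bounds voxels are filled with −1000 HU (air). The crop is
   recorded (`CropRegion`) so inferred masks can be padded back exactly.
3. **Metal artefact removal**: voxels above a threshold (default 2000 HU) are
   masked, the mask is dilated by a physical radius (default 3 mm,
   spacing-aware), smoothed with a 1-voxel Gaussian, re-thresholded at 0.5,
   and every masked voxel is replaced with soft tissue (default 50 HU). The
   procedure is idempotent because the replacement value is below the
   threshold. The clinical constants are unpublished; all three are
   config-exposed and the defaults are conventional values.
4. **Two-channel window/level normalisation**: channel 1 a wide thorax window
   (W1600, L−200), channel 2 a narrow cardiac soft-tissue window (W200, L65).
   Each maps `[L−W/2, L+W/2]` linearly to `[0, 1]` with clipping — monotone in
   HU by construction. The output range is a package choice; the windows are
   the clinical ones.
5. **Segmentation** with a compact 3D residual UNet (below), yielding five
   classes: background + the four substructures.
6. **Postprocessing**: per-structure binary opening with a spherical element
   (default radius = the smallest voxel spacing) followed by removal of
   connected components smaller than 0.05 cm³ (26-connectivity), *then* union
   into the CAA, then padding back to the original matrix. Cleaning precedes
   the union because opening a union behaves differently around the thin
   coronary tubes. Both parameters are config-exposed; the clinical values
   are unpublished.
7. **Output**: NIfTI masks plus optional DICOM RT-Structure export
   (slice-plane polygonisation of each mask at the 0.5 level; re-rasterising
   the written contours reproduces convex structures with DSC ≥ 0.99).

## The network and its training

The segmenter is a 3D UNet with residual blocks: per level, two 3×3×3
convolutions with instance normalisation and ReLU plus an additive skip
(1×1×1 convolution where channel widths differ); 2× average-pool
downsampling; trilinear (separable half-voxel-aligned linear) upsampling with
encoder-feature concatenation; a 1×1×1 output head. Defaults: depth 3, 16
base features doubling per level (the `desk` profile uses 4 base features).
Depth, widths, normalisation and upsampling mode are all config-exposed.

The loss is the weighted multiclass soft Dice over softmax probabilities,

    D_c = (2 Σ p_c g_c + ε) / (Σ p_c + Σ g_c + ε),   loss = 1 − Σ w_c D_c / Σ w_c,

with ε = 1e-5, optimised with Adam (default lr 1e-3; desk profile 3e-3).
Cases are split 80/20 into training/validation by a seeded shuffle; the seed
also covers weight initialisation and epoch shuffling, so training is fully
deterministic on a single thread and a repeated run reproduces the loss
history exactly.

Default class weights are **uniform**. The per-class normalisation inside
each Dice term already equalises large and small structures, so extra
inverse-volume weighting (provided as `inverse_volume_weights`, with a
tempering exponent) mostly removes weight from the background term — and it
is the background term that pushes background probability *down* inside the
structures. With the background starved, training can reach a low soft-Dice
loss whose argmax is still background everywhere (a diffuse-probability
plateau); with uniform weights the optimisation is stable across seeds. This
was established empirically on phantom training runs and is exercised by the
training-sanity test.

The compute backend is NumPy with hand-written backward passes (im2col GEMM
convolutions, exact adjoints for pooling/upsampling; all verified against
numeric and adjoint oracles in the test suite). Inference is CPU-only by
construction. ONNX export is surfaced as an optional operation that raises a
clean capability error in this build, which ships no ONNX exporter/runtime.

## Consensus (STAPLE)

`consensus.staple` implements simultaneous truth and performance level
estimation: per-voxel latent truth `T`, per-rater sensitivity `p_j` and
specificity `q_j`, EM alternation in log-space with a global scalar foreground
prior γ (default: the raters' mean foreground fraction). Initialisation
p = q = 0.99999, convergence when the mean |ΔW| over the grid falls below
1e-7, at most 100 iterations; the incomplete-data log-likelihood is recorded
per iteration and is non-decreasing (EM guarantee, asserted in tests).

For tractability the dense computation is restricted to the union bounding
box dilated by 10 mm. Voxels outside it are all-background for every rater,
so they share a single analytic posterior which is carried exactly through
the E-step, M-step and log-likelihood — the restricted computation equals a
full-grid run to floating-point precision (tested). STAPLE is applied per
structure; multi-label STAPLE is out of scope.

## Geometric metrics

A surface is the set of centres of foreground voxels with at least one
background 6-neighbour; the grid boundary counts as background. MSD is the
symmetric pooled mean of nearest-point distances between the two surfaces; HD
the maximum over both directed sets; HD95 the 95th percentile with linear
interpolation of the *pooled* bidirectional distance multiset (pooling is
consistent with the MSD definition; taking the max of directed percentiles is
the rejected alternative). Distances use the exact Euclidean distance
transform with anisotropic spacing and agree with an O(n²) all-pairs oracle
to 1e-9 mm. DSC of two empty masks is 1.0; empty-vs-non-empty is 0.0, and
surface distances for empty masks are an error (reported missing, never
silently 0).

## Dosimetry

Volume-referenced dose metrics are computed from exact sorted in-structure
voxel doses; binned DVH curves (default 0.1 Gy bins) exist only for plotting.
`Dx%` is the largest dose covering at least x% of the structure; `VxGy` the
percentage receiving ≥ x Gy; `1-cc max` the largest dose covering ≥ 1 cm³;
`1-cc min` — whose clinical convention is not published — is interpreted as
the near-minimum after excluding the coldest volume beyond 1 cm³ (the mirror
of 1-cc max). Structures below 1 cm³ make 1-cc metrics an explicit
undefined-metric error. The default panel covers PTV coverage (1-cc min,
D95, 1-cc max, mean), spinal cord max / 1-cc max, Lungs−PTV V5/V10/V20 Gy,
Lungs−ITV mean, heart V30/V40 Gy, CAA max / 1-cc max, and oesophagus
mean / V55 Gy, with set-difference structures computed on the fly. Internal
unit is Gy; a cGy converter is provided.

## Interobserver statistics

Each validation metric is modelled as
`y_ij = β0 + β1·I(auto) + b_i + ε_ij` with patient random intercepts. Both the
full and the reduced (no contour-type) model are fitted by **maximum
likelihood** via the profiled likelihood on the variance ratio
λ = σ_b²/σ² (per-patient Sherman–Morrison; 1-D grid + bounded refinement over
log λ, with λ = 0 evaluated exactly). ML rather than REML is used throughout
because the likelihood-ratio test of a fixed effect requires both fits to
maximise the same likelihood; the profiled search guarantees
ll_full ≥ ll_reduced. The LRT statistic is referred to χ²(1). Degenerate
zero-spread data fit at the σ_b² = 0 boundary with a residual-variance floor
of 1e-12, so constant columns yield statistic 0 and p = 1 rather than a
failure. Fits agree with statsmodels' `MixedLM(reml=False)` to ~1e-5.
Bonferroni and Holm adjustments are reported alongside unadjusted p-values;
the primary significance level is α = 0.05 unadjusted.

The observer-spread summary is the sample SD (n−1) over manual observers
computed per patient, then averaged unweighted over patients; patients with a
single manual observer are excluded with a warning.

## Synthetic phantoms and simulated observers

The phantom emulates a planning thorax CT with geometric primitives: an
elliptical body with a subcutaneous fat ring, two lung ellipsoids, a
vertebral column with spinal cord, an oesophagus, a heart ellipsoid between
the lungs, and — inside the heart — the right atrium (ellipsoid), aortic
valve root (cylinder), and two 7 mm × 2 cm coronary tubes leaving the valve
root in different directions. A lung tumour provides PTV/ITV targets. Tissue
HU values are conventional (lung −800, soft tissue/myocardium 40, contrast
blood 200, fat −80, bone 700, metal 3000); with IV contrast off, the blood
pool equals myocardium. Smooth Gaussian HU noise (sd 12) and per-case
geometric jitter (±3 mm) provide case variety; labels are mutually exclusive
by construction. Default grid 128×128×64 at (1.5, 1.5, 3.0) mm so the crop
stage runs unscaled; the desk profile is 64×64×32 at (3, 3, 6) mm — the same
physical extent at a CPU-friendly resolution.

Simulated manual observers shift the true boundary (signed-distance
threshold) by a signed bias plus a correlated Gaussian field (default sd
1.5–2 mm, correlation length 12 mm), mimicking smooth human disagreement;
Bernoulli voxel flips are a separate generator reserved for STAPLE
recovery experiments, where sensitivity/specificity are known exactly. The
synthetic dose emulates a CAA-sparing plan: prescription (55 Gy) over the
PTV, exponential falloff with distance (22 mm scale), smooth noise, and a
smooth cap at the CAA maximum-dose objective (19.5 Gy) inside the CAA.

**What the phantoms do not show.** They contain no real anatomy, no texture,
no motion blur, no streak artefacts, and their contrast between substructures
and myocardium is cleaner than clinical imaging. Passing the phantom suite
demonstrates that the *machinery* is correct (metrics, EM, mixed model,
training dynamics, determinism), not that the network generalises to patient
CT — at desk scale the segmentation task is intentionally much easier than
the clinical one, which is why held-out CAA DSC on phantoms (≳0.95) sits far
above clinically reported auto-contouring accuracy.

## Commissioning run and problem sizes

`commissioning.run_commissioning` mirrors the three-phase validation:
training (separate), commissioning (this run), and a clinical-monitoring
analogue (`compare_edited` on auto vs edited masks; Likert ratings ingested
from CSV and summarised as per-score fractions plus the "Good or better"
fraction). Per case it segments, builds the STAPLE consensus of the simulated
observers' CAA, scores all contours against the consensus (MSD/DSC/HD95),
generates one synthetic plan per contour (same per-case noise seed, so plans
differ only through the contour) evaluated on the consensus CAA, and fits the
mixed model per metric. A gross failure is flagged when the auto CAA is empty
or its centroid lies more than 50 mm from the localised heart centre — an
operational proxy for "no overlap with the actual CAA". Stage failures are
recorded per case and the run continues.

Problem sizes are chosen for a single-CPU workflow: 20 desk phantoms for
training (16/4 split, 30 epochs, ~2–3 min), 10-case commissioning cohorts
with 3 observers each (~10 s), STAPLE recovery on 48³ grids, 200–500
replicates for the mixed-model calibration studies. Reports are written with
fixed float formatting and sorted keys, so a repeated run under the same seed
is byte-identical.

## Known limitations

* Axis-aligned geometry only; tilted/oblique acquisitions are rejected, not
  resampled.
* The RT-Structure writer targets contour transfer, not full DICOM
  conformance (no holes/keyhole encoding, no registration objects).
* The NumPy training loop is practical at phantom scale only; clinical-scale
  training would need a GPU framework, though the architecture and loss are
  identical in form.
* The heart-localisation heuristic presumes a thorax with two air-filled
  lungs and soft tissue between them.
* The dose generator is a geometric surrogate — no beam model, no optimiser;
  it supports commissioning-machinery validation, not planning research.
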