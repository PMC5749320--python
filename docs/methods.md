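# Methods

## Problem and model

Follicular adenoma and follicular carcinoma are differentiated
histologically by capsular/vascular invasion at the lesion periphery, so
the classifier is built to see *only* the periphery. Each nodule is
represented by the set of 50×50-pixel patches centered at every pixel of
its closed margin contour. A small CNN assigns each patch a two-class
posterior; the nodule's label is the class with more patch-level hard
votes (exact ties go to carcinoma — the clinically conservative call — and
are flagged). Majority voting makes the nodule decision an ensemble over
hundreds of weakly correlated looks at the same margin, which is what lets
a model trained on a few dozen nodules produce stable nodule-level calls.

Coordinates are 0-based `(row, col)`, origin top-left. A `size`×`size`
window centered at `(r, c)` covers the half-open ranges
`[r − size//2, r + size//2)` × `[c − size//2, c + size//2)`; windows that
would leave the image are discarded and counted, never padded — padding
would inject non-ultrasound statistics into the margin band.

## Normalization

All normalization statistics (min, max, mean) are per patch. Training
patches get mean-zero min-max normalization
`v = (u − E[u])/(max u − min u)` (exactly zero-mean, values in [−1, 1]).
Test patches get the α-parameterized form
`q = (p + α·E[p] − min p)/(max p − min p)`, which is plain min-max scaling
at α = 0 and is affine in α with per-pixel shift `α·E[p]/(max − min)`.
The per-patch reading of `E[·]` is the only one under which the α = 0 ⇒
min-max identity holds exactly, and it keeps train/test preprocessing
self-contained per patch; a per-position mean image over the training set
(AlexNet-style) is a possible alternative reading that we do not adopt.
The training formula is implemented as scale-then-center; the literal
variant `(u − E[u] − min)/(max − min)`, which differs by the constant
`min/(max − min)`, is available as `variant="literal"` for sensitivity
checks. Constant patches (min = max) are dropped with a logged count, not
imputed.

α is an operating-point control: shifting all pixels of a patch moves the
classifier's vote, so sweeping α traces per-nodule benign-percentage
curves, and the induced (FPR, TPR) pairs — deduplicated, anchored at
(0,0)/(1,1), sorted by FPR — form an ROC integrated by the trapezoidal
rule. "Mean curves" are arithmetic means across nodules of per-nodule
benign percentages at each α, separately per true class. Distinct α per
cohort is supported as a `cohort → α` map; the fine-tuning helper picks α
by exhaustive scan of nodule-level accuracy on a held-out cohort (ties
broken toward smaller |α|).

## Patch classifier

Reference architecture (`channel_scale = 1`): five 3×3 stride-1
same-padding convolutions of 16, 256, 512, 2048, 4096 channels with ReLU,
2×2/2 max pools after the second and fifth, then dense 512, dense 256 with
dropout 0.5, and a 2-unit softmax. Only the pools downsample
(50 → 25 → 12 with floor). At full width this is ~3×10⁸ parameters;
`channel_scale` divides every conv channel count and hidden dense width
(floor division, error if any width falls below 1, so the maximum scale for
this stack is 16 → conv 1/16/32/128/256, dense 32/16/2).

Training is plain SGD (no momentum) on softmax cross-entropy with
epoch-shuffled batches; weights use fan-in-scaled Gaussian initialization;
dropout is inverted and disabled at inference. Initialization, shuffling
and dropout draw from named substreams of one seed, so runs are
bit-reproducible and checkpoints (single zip of weights + config +
architecture fingerprint) reload to identical predictions. The network is
implemented directly in NumPy: float32 im2col + GEMM convolutions, a
9-shift scatter-add for the convolution input gradient, and argmax-routed
pool gradients. Reference hyperparameters are 380 epochs, batch 400,
learning rate 1e-4, dropout 0.5; no class rebalancing is applied.

## Synthetic phantoms

The generator emulates what the pipeline needs from clinical B-mode
exports, not acoustic physics:

* **speckle**: a piecewise-constant template multiplied by Rayleigh noise
  (normalized to unit mean, shape configurable) then Gaussian-blurred
  (σ = 1 px) to mimic resolution-cell correlation — a standard phantom
  recipe;
* **geometry**: a hypoechoic radius-perturbed ellipse (semi-major axis
  80–105 px, axis ratio 0.78–0.98, image 370 px) with an 8 px rim band
  inside its boundary. The ground-truth contour is the perturbed boundary
  traced to a closed 8-connected pixel path (no annotator noise by
  default; a jitter parameter exists);
* **class contrast, rim only**: adenomas get a smooth, regular, bright rim
  (low radial perturbation); carcinomas an irregular one (higher
  perturbation amplitude, angular intensity modulation, and randomized rim
  interruptions). Interiors and backgrounds share statistics across
  classes, so any classifier success on margin patches — and failure on
  interior patches — evidences margin-localized features;
* **cohorts**: each image is affinely rescaled toward its cohort's target
  mean intensity (defaults 63.819 for "A", 82.07 for "B", emulating two
  clinics whose acquisition settings differ in global brightness) and
  quantized by
  round-half-away-from-zero to 8 bits.

The nodule radii are sized so the interior-control contour exists: a 50 px
patch reaches 25√2 ≈ 35.4 px from its center, so sampling rim-free interior
requires an inset of ≥ rim width + 35.4 px (default 50 px), and the
smallest semi-minor axis (0.78 × 80 px, minus perturbation) must stay above
that inset. Phantoms are defined in pixel units only; no physical
calibration is modeled.

What passing on phantoms does **not** show: robustness to real speckle
statistics, acquisition-protocol variation beyond a global brightness
shift, annotator variability in contours, or lesions whose discriminative
features are interior (e.g. calcifications).

## Desk-scale experiment sizes

The margin-localization experiment (used by the test suite and
`scripts/acceptance.py`) runs the full pipeline at sizes a single CPU
handles comfortably: `channel_scale` 16, 12+12 training nodules (cohort A)
with 5 variance-selected patches each, 4+4 held-out nodules (cohort B,
~4,400 margin test patches), 30 epochs, batch 16, learning rate 1e-3 —
chosen for training convergence of the narrow network (final training
accuracy ≈ 0.96) — and an α fine-tuning grid of {−1.5, −0.75, 0, 0.75,
1.5}. Because plain SGD from a narrow random init occasionally stalls (the
1/16-width first layer is a single 3×3 filter), training runs 3 independent
restarts and keeps the fit with the lowest final *training* loss; no test
information enters that selection. The interior control repeats the
identical protocol on inset contours. The variance-ranked training selection concentrates on
high-contrast rim patches, which shifts the test-time vote distribution
toward carcinoma at α = 0; the fine-tuned α compensates, which is exactly
the operating-point role the parameterization is designed for.

## Design choices made where the design was open

* Manual "distinctive patch" training selection is replaced by a
  deterministic surrogate: rank in-bounds candidates by within-patch
  intensity standard deviation, keep greedily subject to a minimum spacing
  in contour path-steps, break ties by contour order.
* G-mean is the geometric mean of precision and recall,
  `sqrt(PPV·TPR)` (the Fowlkes–Mallows index), not `sqrt(TPR·TNR)`; only
  the former is consistent with the reference panel values this package
  reproduces (G-mean 0.7452 alongside PPV 0.76 and TPR 0.7308).
* Metrics with zero denominators are reported as undefined (`None`,
  rendered "-"), never coerced to 0 or 1.
* Fixed train/test partition (train on one simulated clinic, test on the
  other); no cross-validation.
* The on-disk contour convention is `[x, y] = [col, row]`; the swap to
  `(row, col)` happens exactly once, in the IO layer.

## Known limitations

The NumPy network is CPU-bound: the reference width is buildable but not
trainable at realistic epoch counts, hence `channel_scale`. Nodule-level
accuracy on a handful of held-out phantoms is granular (1/8 = 12.5%
steps), so single-seed nodule-level numbers carry wide intervals; the
patch-level binomial test is the statistically powered endpoint. ROC
curves built from a coarse α grid have few distinct operating points, and
their trapezoidal AUC is correspondingly coarse.
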