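# Methods

## Problem and model

The package discriminates comatose patients from healthy controls using
one whole-brain scalar volume per subject and MR index.  Six indices are
handled: gray-matter volume (GM), raw T1-weighted intensity (T1),
fractional anisotropy (FA), mean diffusivity (MD), and two seed-based
resting-state connectivity maps (posterior cingulate, rsPCC; precuneus,
rsPreCun).  One network is trained per index; a per-subject majority
vote fuses the six predictions.

The classifier is a fixed 3D CNN (an AlexNet/VGG-style 3D cascade):

| stage | spec |
|---|---|
| conv1 | Conv3D, 32 filters, 3x3x3, stride 1, valid + BN + ELU |
| pool1 | AvgPool3D 3x3x3, stride 3 |
| conv2, conv3 | Conv3D 64 + BN + ELU (each) |
| pool3 | AvgPool3D 2, stride 2 |
| conv4-6 | Conv3D 128 + BN + ELU (each) |
| pool6 | AvgPool3D 2, stride 2 |
| fc1 | 512 + BN + ELU + Dropout 0.5 |
| fc2, fc3 | 512 + BN + ELU + Dropout 0.25 |
| fc4 | 512 + BN + ELU |
| fc5 | 2 + softmax |

Valid convolutions shrink every spatial dimension by 2 and pooling
divides by its stride (floor), so the smallest admissible input grid is
62 voxels per dimension.  On the 2-mm template grid (91, 109, 91) the
flatten length is 4608 and the model holds 4,432,386 parameters, of
which 4,427,202 are trainable; the remainder is exactly the batch-norm
running statistics (2 per normalized channel).  `count_parameters`
implements this closed form independently of the layer stack, and the
two are cross-checked in the tests.

Training protocol (defaults of `CNN3DClassifier`): 100 epochs,
mini-batches of 8, categorical cross-entropy, Adam at 5e-5 with the
learning rate halved after 5 epochs without progress of the training
loss (floor 1e-7), and L2 weight decay of factor 5e-4 applied to conv
and FC kernels only (Keras convention: `factor * sum(W^2)` added to the
loss).  Inputs are normalized per index to [0, 1] using the global
minimum/maximum over all voxels of the *training split only*; test
intensities outside the training range are clipped into [0, 1].

## Implementation choices

The network is implemented directly on numpy (im2col + BLAS batched
GEMM for the convolutions, numba-fused kernels for the ELU and the
batch-norm backward pass, float32 throughout).  Choices the protocol
leaves open, fixed here:

* **Initialization**: He-uniform for conv/FC kernels (standard for the
  ELU family), BN scale 1 / shift 0, biases 0.
* **BN**: epsilon 1e-3, applied before the ELU.  Running statistics
  default to a *cumulative* average of batch statistics rather than an
  exponential moving average: with an EMA and momentum 0.99, short
  desk-scale runs would end inference on statistics still dominated by
  their initialization.  A fixed momentum is selectable (`bn_momentum`).
* **Plateau monitoring**: the training loss (no inner validation split),
  reduction factor 0.5, patience 5, min-delta 1e-4.
* **L2**: kernels only, never biases or BN parameters.
* **No augmentation, no early stopping.**
* Inference (and activation retrieval) always uses frozen running
  statistics and disabled dropout, so predictions are deterministic and
  independent of batch composition.

## Evaluation

Tenfold cross-validation repeated 10 times (100 test folds) per index.
Folds are class-stratified — with 29 patients vs 34 controls,
unstratified folds can produce single-class test folds that leave
sensitivity or specificity undefined — and a single fold plan is reused
across all indices so the majority vote is well-defined per subject.
Per fold: normalization fitted on the training split, a fresh network
trained, the test split scored.  Metrics (accuracy, sensitivity,
specificity, PPV, NPV with "coma" positive) come from the standard
formulas with zero-denominator ratios reported as missing, never 0.
AUC is the rank statistic (ties counted half) on the softmax
probability of the positive class by default; a hard-label scoring mode
is selectable because published summaries of this design sometimes
coincide with accuracy, which suggests label-based scoring.  The ROC
operating point maximizes sensitivity + specificity (Youden), ties
broken toward the higher threshold.  Summaries are mean (SD, 95% CI)
over fold values, CI = mean ± 1.96·SD/√n (t-quantile selectable), with
[0, 1]-truncated bounds reported alongside.

Per-subject labels are the majority over that subject's
one-per-repetition test predictions (tie → mean probability).  Majority
voting fuses the per-index subject labels; 3-3 ties fall back to the
mean positive-class probability and are flagged.

The outcome audit counts, per index, the false negatives (patients
labeled control) and the fraction of them with a favorable 3-month
outcome, as a round-half-up integer percentage; indices without false
negatives report a missing rate.

## Visualization maps

For each of the six conv blocks the post-BN+ELU output is retrieved in
inference mode, negative activations are discarded, filters are
averaged, and the map is trilinearly interpolated to the input grid.
The interpolation convention matters and is fixed as follows: cell i of
a tapped map is placed at its receptive-field center
`offset + spacing * i` in input coordinates (conv3: spacing 3, offset
8; conv6: spacing 6, offset 27.5), with edge replication outside the
covered span, so constant fields are preserved exactly.  Plain
stretch-to-full-extent resizing is also available but is geometrically
wrong for a valid-convolution cascade — its 20-30% scale error
displaces peripheral structure by several voxels at depth, which we
measured directly as a loss of localization.  The six per-block maps are
averaged into one subject map.  Per class, subject maps of correctly
classified *training* subjects are averaged; the two class means are
min-max normalized to [0, 1] on a *joint* scale (shared minimum and
maximum over both maps), and their absolute difference is thresholded
at half its maximum.  The joint scale matters: normalizing each class
map independently rescales them differently whenever their ranges
differ (the patient map's range is inflated by the effect), which
floods the difference map with background and suppresses the true
contrast — we verified this empirically, and per-map and z-score modes
remain selectable for comparison.  Maps are
computed per fold on training subjects only and reported for one
designated repetition (per-fold difference maps averaged over that
repetition's folds, then re-thresholded).  Localization is quantified
as the Dice overlap between the thresholded mask and the generator's
injected ROI, calibrated against a null in which an equally sized ROI
is relocated uniformly at random inside the brain mask.

## Synthetic cohort

Real volumes for this task are not publicly available, so the package
ships a generator whose defaults emulate the study conditions: 34
controls + 29 patients, six index volumes each, with per-patient
3-month outcome labels.  Each volume is

    smooth low-frequency texture  +  effect * noise_sd * ROI  +  white noise,

zeroed outside an ellipsoidal brain mask (~33% of the grid).  The
texture is a Gaussian random field (FWHM 6 voxels) scaled to SD 0.5,
drawn per subject from the same generator for both classes, so the
injected effect is the only class signal.  The effect is a mean shift
of `effect_size * noise_sd` (Cohen's-d-like; default 3, noise SD 1)
added *after* smoothing, inside an index-specific ellipsoidal ROI
(semi-axes 13% of the grid, ~2% of the volume — a deliberately diffuse
footprint, consistent with the widespread injury pattern of anoxia);
the six ROIs are pairwise disjoint and index-specific in location
(deep/central for FA, anterior for MD, posterior-medial for the two
resting-state indices), so per-index localization is checkable.
Patients with a favorable outcome have the effect multiplied by an
attenuation factor (default 0.5), encoding the hypothesis that patients
on a recovery trajectory already resemble controls — which is what
makes the outcome audit testable.  Randomness is split per
(subject, index) by counter-based seed-sequence keys, so cohorts are
reproducible and independent of generation order.

The texture SD (0.5) reflects that template-space anatomy is largely
shared across subjects: per-subject anatomical deviation is weaker than
the voxel noise.  Stronger per-subject textures make tiny-cohort
training degenerate into subject memorization, which is a statement
about tiny cohorts rather than about the method; the defaults are
chosen so that the generator's parameter-recovery surface (large
injected effect ⇒ high CV accuracy; zero effect ⇒ chance) holds at
desk scale.

What the generator does **not** model: BOLD or diffusion biophysics,
tissue classes, lesion topography, registration error, motion or
scanner artifacts.  Passing recovery tests therefore demonstrates that
the pipeline finds and localizes a known injected signal end to end —
not that it would achieve any particular accuracy on clinical data.

## Problem sizes

The reference protocol ("full" profile: 91×109×91 grid, 100 epochs, 10×10
CV, 63 subjects, six indices) is faithful but amounts to ~600 trained
networks; with this CPU implementation a single such network is hours
of work, so tests and the acceptance script use desk-scale runs: 10
controls + 10 patients at 64³ (8 + 8 for the zero-effect control), one stratified 2-fold split, 6 epochs,
batch 5, Adam 2e-4 (a step size that makes a handful of epochs meaningful; the
reference 5e-5 is tuned for 100 epochs).  The thresholds the
experiments are held to (CV accuracy ≥ 0.9 at effect 3, chance-level
binomial band at effect 0, fused accuracy within 0.05 of the best
index, Dice above the 99th percentile of the relocated-ROI null) do not
depend on these sizes.  Built-in profiles: `full`, `desk` (64³, 20
epochs, 10×10 CV), `smoke` (64³, 5 epochs, 2×3 CV, two indices).

## Known limitations

* The input grid of the reference design is inferred: (91, 109, 91) is
  adopted because it uniquely reproduces both published parameter
  totals.
* Whether activations were read before or after BN+ELU, how class maps
  were normalized, and how 3-3 voting ties were resolved are not
  specified by the reference; the choices above are recorded as
  configuration.
* The quantity monitored for LR decay is unspecified; training loss is
  used.
* Grids are never resampled; mismatched grids are an error by design.
* The stochastic recovery thresholds are evaluated on small cohorts;
  individual per-index accuracies fluctuate, which is why the recovery
  check is the mean over the informative indices.
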