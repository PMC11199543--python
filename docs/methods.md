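# Methods

`oclnet` implements a supervised pipeline for delineating a single cystic
lesion in a 3-D cone-beam-CT-like volume: a U-Net-style encoder–decoder
with a dense multi-scale attention mechanism, a two-phase training schedule
that re-crops its own inputs around the predicted lesion, and a combined
cross-entropy + size-aware Dice objective.  Because no public CBCT cohort
with lesion masks exists, the package ships a parametric jaw-phantom
generator, and every experiment in the test suite and the acceptance
script runs on phantoms generated at run time.

## Segmentation network

The backbone is a five-level 3-D encoder–decoder (`num_levels=5`,
`base_channels=32` by default).  Each level is a block of two
(3×3×3 convolution → per-channel normalization → ReLU) stages; channels
double per level.  2×2×2 max pooling descends between encoder levels, with
dropout (rate 0.2) after each pooling; kernel-2/stride-2 transposed
convolutions ascend, and skip connections concatenate encoder features
into the same-level decoder block.  A 1×1×1 convolution + sigmoid head
yields voxelwise lesion probabilities.  Convolutions that feed a
normalization layer carry no bias term (the normalization's mean
subtraction cancels a constant channel shift exactly, which would leave
such biases without gradient).

**Multi-scale dense attention.**  At the `attention_scales` coarsest
decoder-side resolutions (`input/2^k` for `k = attention_scales … 1`;
default 4 on the five-level network, so maps at 1/16 … 1/2 resolution), a
1×1×1 convolution + sigmoid produces a single-channel spatial attention
map in [0, 1].  Every map is propagated densely: nearest-upsampled and
concatenated into the input of each subsequent (finer) decoder block, so
the decoder at every scale sees all coarser attention signals.  Setting
`attention_scales = num_levels` (the all-scales ablation) adds a
full-resolution map concatenated just before the output head;
`attention_scales = 0` disables the module and recovers the plain
backbone.  Sigmoid (rather than unbounded) maps keep the dense
concatenation scale-stable; concatenation (rather than multiplicative
gating) lets the decoder learn how to use each signal.

**Deep supervision.**  The attention maps double as per-scale probability
outputs.  With `deep_supervision` on (default) each map is compared to a
block-maximum-downsampled ground-truth mask — a coarse cell is foreground
when *any* of its fine voxels is.  Point-sampled downsampling was tried
first and rejected: lesions a few voxels across vanish at 1/4 resolution
(measured: 4 of 20 phantoms at the coarsest scale of the desk preset), and
the per-scale targets then train the attention maps toward all-zero on
exactly the small-lesion cases the mechanism exists for; full-cohort
training collapsed to background-only predictions.  The combined loss is
averaged with equal weight over the main output and all supervised scales,
so a perfect prediction still attains the loss minimum of −1.

**Normalization.**  Batches contain one volume, so batch statistics are
instance statistics.  By default running means/variances are tracked and
used at evaluation (batch-norm behaviour).  The desk-scale preset sets
`instance_norm=True`: evaluation also normalizes by the current input's
statistics.  With small, diverse cohorts the running averages match no
individual volume and evaluation-mode predictions degrade badly; instance
behaviour removes the train/eval mismatch.  Both modes share one interface
and parameter count.

## Losses and metrics

For a probability map `P` and binary truth `Y` with soft sizes
`|P| = ΣP`, `|Y| = ΣY`:

    l_bce = mean voxelwise cross-entropy   (P clipped to [1e-7, 1 − 1e-7])
    l_sd  = min(|ΣP − ΣY| / ΣY, 1) − 2·Σ(P·Y) / (ΣP + ΣY)

`l_sd` ranges over [−1, 1]: the clamped first term penalizes the relative
size error (so an arbitrarily oversized prediction cannot blow up the
loss), the second is the soft Dice overlap, and the minimum −1 is attained
iff `P = Y`.  The size term reads `|P − Y|` as a *scalar* difference of
soft sizes, matching its role as a size-difference ratio; it is not a
voxelwise set difference.  The total loss is `l_bce + l_sd`, averaged (not
summed) over the batch so its scale is batch-size independent — with the
protocol's batch size of 1 the two conventions coincide.  Samples or
supervision scales whose ground truth is empty (possible for degenerate
crops) contribute their cross-entropy term only; `size_aware_dice_loss`
itself rejects empty ground truth as a contract violation.

Evaluation uses Dice `2|A∩B|/(|A|+|B|)` and IoU `|A∩B|/|A∪B|` on the
prediction binarized at 0.5 (strict `>`), both defined as 1.0 when truth
and prediction are empty, plus the voxelwise ROC AUC in its rank
(Mann–Whitney) form with ties at half credit.  Dataset-level numbers are
unweighted means of per-volume values; volumes whose truth is single-class
are excluded from the AUC mean.

## Auto-adapting crop schema

After `adapt_epoch` epochs the model's own thresholded predictions drive
input regeneration: predicted mask → nearest-upsampled to `upscale_shape`
(default 256³ against 128³ inputs, i.e. factor 2) → tightest bounding box
→ a `crop_shape` window centred on the box centroid cut from the
equally-upsampled image, padded with the image minimum where it overruns.
Mode `S` keeps `crop_shape` equal to the network input, so phase-2 volumes
have the original size but double effective resolution around the lesion;
mode `D` crops at native resolution (ablation).  Ground-truth labels are
cropped with the identical transform so phase-2 supervision stays aligned.

Edge policies: the centroid rounds down on ties and the window start
rounds up on even sizes, so a box exactly the window size stays contained;
predictions with fewer than `min_fg_voxels` (10) foreground voxels, or an
empty box, fall back to the whole field of view (the original volumes
resampled to `crop_shape`) rather than a blind centre crop — a centre crop
of the upscaled grid covers only its middle eighth and can silently drop a
peripheral lesion from the ground truth; boxes larger than the window are
resampled down into it.  Each volume's box, fallback flag and
lesion-retention fraction are recorded in an `AdaptReport`.

**Two-stage inference.**  A model trained through the schema expects
lesion-centred crops, so deployment is two-stage: the *boundary-epoch*
weights (saved as the phase-1 checkpoint) segment the full volume to
locate the lesion, the crop schema extracts the window, the final weights
segment the crop, and the prediction — mask and probability grid — is
mapped back onto the native grid (`restore_to_native`), with zeros outside
the window.  Locating with the final weights instead was tried and
rejected: after the boundary the network trains only on lesion-centred
crops and its full-volume localization drifts badly off-distribution
(measured 0.58 vs 0.93 mean held-out Dice).  Held-out metrics are always
computed on the native grid against unmodified ground truth, so adapted
and single-phase models are scored identically.

## Training protocol

Adam (lr 1e-4 full scale), batch size 1, 200 epochs with adaptation at
epoch 100, weights carried across the boundary (no re-initialization), no
augmentation, no learning-rate schedule, no early stopping; an 80/20
random train/test split.  Validation Dice on the held-out split is
recorded every `val_every` epochs, purely observationally.  All
randomness — weight initialization, shuffling, dropout — derives from one
seed; identical configurations reproduce identical histories.  A
non-finite loss aborts with a diagnostic.

## Phantoms

Each phantom embeds, in a `shape` grid (desk scale 32³): a half-torus
"jaw arch" of elevated intensity (0.85) against soft-tissue background
(0.10); 4–8 hyperintense spheres (1.0) along the arch crest as teeth-like
distractors; and one hypointense (0.25) axis-aligned ellipsoidal lesion
centred on the arch tube, with additive Gaussian noise (sd 0.04) on the
image only.  The mask is the exact ellipsoid voxelization, giving an
analytic volume oracle.  Four profiles span the clinical variability the
attention module targets: `small_crown` and `small_apical` (radius
0.045–0.075 of the extent, placed near the crown resp. root side of the
arch), `medium` (0.08–0.12) and `large` (0.13–0.19), cycled in generated
datasets.  Intensities are scale-free (no Hounsfield calibration), there
is no beam-hardening or artefact model, and profiles encode size/location
only — no subtype texture.  Passing tests therefore demonstrate the
machinery (geometry handling, optimization, the crop schema's benefit),
not clinical-grade performance on real CBCT.

## Desk-scale study conditions

All tests and the acceptance script run a reduced preset chosen to fit a
single CPU: 3 levels, 8 base channels, 2 attention scales, 32³ inputs
(≈86 k parameters), instance-mode normalization, upscale 64³ / crop 32³.
The main study trains on 60 phantoms split 48/12 for 40 epochs with
adaptation at epoch 20 (the acceptance script reruns it at 40 phantoms,
split 32/8, to fit its runtime budget).  The preset's learning rate is
3e-3 — raised relative to the full-scale protocol because the network is
three orders of magnitude smaller, but below the oscillation threshold
observed on diverse cohorts; the single-phantom overfit check uses 1e-2
for 200 steps.  The ablation-direction comparison (full model vs plain
backbone) runs at a further reduced scale — 24³ volumes, 12 phantoms,
12 epochs — so three seeds per arm stay affordable.

**What the phantom study can and cannot show.**  The two-phase pipeline
reaches mean held-out Dice above 0.9 under the main study conditions, the
crop schema retains every lesion with oracle masks, and the loss behaves
as designed.  The ablation *direction*, however, does not reproduce on
phantoms: the plain backbone already solves the synthetic task near its
ceiling (≈0.99 Dice), leaving no headroom for the attention, size-loss and
crop additions, whose value on real CBCT stems from anatomical and
textural heterogeneity the phantom deliberately omits.  Two desk-scale
effects compound this: the size term's gradient is spatially uniform with
magnitude 1/|Y|, which for lesions tens of voxels large overwhelms the
overlap term's spatial signal, and mode-S inference pays a
resample-roundtrip boundary cost that direct single-phase prediction does
not.  The full-vs-backbone comparison is still computed and reported, but
on this synthetic task its ordering reflects those phantom-scale effects,
not the method's clinical merit.

## Numerical choices and limitations

Trilinear resampling is cell-centred (`grid_mode`), preserving constants
and, for nearest-neighbour integer-factor upscaling, scaling foreground
counts exactly by the volume ratio.  Mask resampling is always nearest
(binary in, binary out).  Intensities are min–max scaled to [0, 1] per
volume before entering the network.  Probabilities are clipped at 1e-7
before logarithms.  Resampling a volume to a coarser grid and back is
lossy; geometry metadata (spacing, origin) follows the (z, y, x)
convention, zero-based, half-open.

Known limitations: single lesion, single class; no DICOM ingestion
(MetaImage/NIfTI only); no surface-distance metrics; the compute core is
CPU-only and single-volume; phantom realism as above.
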