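# oclnet

Automatic delineation of odontogenic cystic lesions (OCLs) — dentigerous
and radicular cysts, keratocysts, ameloblastomas — in 3-D cone-beam CT
volumes is hard for the usual reasons: the lesion is a small hypointense
blob inside a bright, curved jawbone crowded with teeth, and the four
subtypes vary widely in size and position.  `oclnet` implements a
segmentation pipeline built around three ideas:

1. **A multi-scale dense attention U-Net.**  A five-level 3-D
   encoder–decoder in which the coarsest decoder scales each emit a
   spatial attention map (1×1×1 convolution + sigmoid) that is propagated
   densely — upsampled and concatenated into every finer decoder block —
   so broad localization guides fine delineation.  The maps double as
   deep-supervision outputs against downsampled ground truth.
2. **An auto-adapting crop schema.**  After a preliminary training phase
   the model's own predicted masks are upsampled, bounding-boxed, and used
   to re-crop every input around the lesion at doubled effective
   resolution; training then continues on the lesion-centred crops with
   the same weights.
3. **A size-aware Dice loss.**  The objective per volume is

       L = l_bce(P, Y) + l_sd(P, Y),
       l_sd = min(|ΣP − ΣY| / ΣY, 1) − 2·Σ(P·Y) / (ΣP + ΣY),

   binary cross-entropy plus a Dice loss augmented with a clamped relative
   size-error term, ranging over [−1, 1] with its minimum at P = Y.

Evaluation uses Dice, IoU, and voxelwise ROC AUC.  Because no public
annotated CBCT cohort exists, the package includes a parametric jaw-phantom
generator (bone arch, teeth-like distractors, one embedded ellipsoidal
lesion in four size/location profiles) and all tests run on phantoms
generated at run time.  Volumes are read and written as MetaImage
(.mhd/.mha) or NIfTI.  The compute core — 3-D convolutions with
reverse-mode differentiation, pooling, normalization, Adam — is
implemented in numpy and verified against finite differences, so the whole
pipeline runs on a single CPU; see `docs/methods.md` for the model
details, defaults, and design decisions.

## Worked example

Generate eight 32-cube phantoms, train the desk-scale preset (3 levels,
8 base channels, 40 epochs, auto-adapt at epoch 20) from a config file,
and evaluate with two-stage inference:

```sh
$ oclnet simulate --n 8 --shape 32 --seed 7 --out demo_data
wrote 8 phantom pairs to demo_data

$ head -4 demo_data/manifest.tsv
id      image         label         profile       seed  lesion_voxels
0       img_0000.mhd  lab_0000.mhd  small_crown   7     22
1       img_0001.mhd  lab_0001.mhd  small_apical  7     64
2       img_0002.mhd  lab_0002.mhd  medium        7     326

$ oclnet train --config demo_cfg.yaml --data demo_data --out demo_run
finished: 40 epochs, final loss -0.2673, val dice 0.6484715740097831

$ oclnet evaluate --checkpoint demo_run/checkpoint.npz \
    --locator demo_run/checkpoint_phase1.npz --data demo_data --out metrics.csv
wrote metrics.csv

$ cat metrics.csv
id,dice,iou,auc
0,0.4565,0.2958,0.9999
1,0.7550,0.6064,0.9999
2,0.8317,0.7119,0.9995
3,0.8480,0.7361,0.9996
4,0.7347,0.5806,1.0000
5,0.7778,0.6364,0.9858
6,0.8418,0.7268,0.9997
7,0.8518,0.7419,0.9994
mean,0.7622,0.6295,0.9980
```

The loss (cross-entropy + size-aware Dice) starts near +1 for an untrained
model and approaches −1 for a perfect one; a final training loss of −0.27
after 40 epochs on six training phantoms indicates solid but not saturated
convergence.  The per-volume rows show Dice/IoU overlap of each predicted
mask with the ground truth on the native grid and the voxelwise AUC of the
restored probability map; the small `small_crown` lesion (22 voxels, id 0)
is the hardest, as expected.  `--locator` points at the phase-1 checkpoint
so evaluation follows the same locate → crop → segment → map-back path the
adapted model was trained for.  Larger cohorts (the default study trains
on 48 phantoms) reach mean held-out Dice above 0.9 — see below.

`demo_cfg.yaml` used above:

```yaml
network:  {num_levels: 3, base_channels: 8, attention_scales: 2,
           input_shape: [32, 32, 32], instance_norm: true}
training: {total_epochs: 40, adapt_epoch: 20, learning_rate: 0.003,
           test_fraction: 0.25, seed: 7}
adapt:    {upscale_shape: [64, 64, 64], crop_shape: [32, 32, 32]}
```

`--preset full` selects the full-scale protocol instead (five levels,
32 base channels, 128³ inputs, 200 epochs with adaptation at 100,
Adam at 1e-4, upscale 256³).

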