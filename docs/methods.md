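# Methods

This note documents the models, conventions and numerical choices behind
`refless4dflow`, and what the synthetic phantom does and does not establish.

## Signal model and reconstruction

A non-symmetric 4-point phase-contrast acquisition is modelled per voxel as

    S₀ = M · exp(i φ_b)
    S_e = M · exp(−σ_e² (π/VENC)²) · exp(i (φ_b + π v_e / VENC)),  e = 1..3

with magnitude M, shared background phase φ_b, velocity component v_e along
the encoding axis (AP, RL, FH in that order, mapped to encodings
(1,0,0), (0,1,0), (0,0,1)), and intravoxel velocity SD σ_e. Independent
Gaussian noise of configurable SD is added to every real and imaginary
channel (no Rician preprocessing: the network consumes real/imaginary
images, for which complex Gaussian noise is the natural model).

Reconstruction inverts this exactly:

* velocity: v_e = (VENC/π) · wrap(∠S_e − ∠S₀), with phase differences wrapped
  to the half-open interval (−π, π] so that +VENC maps to +π. Zero-magnitude
  voxels get v = 0 and an `unreliable` flag rather than an arbitrary phase.
* turbulence: σ_e² = f · (VENC/π)² · ln(|S₀|/|S_e|), clipped below at zero
  (the estimator is meaningless where turbulence would have to *amplify*
  signal). The default factor is f = 1, the exact inverse of the forward
  model, so noise-free round trips recover the ground truth to machine
  precision; the classical Gaussian-model estimator (f = 2) is available as
  `sigma_factor="classical"` in both the simulator and `compute_tke`, and
  the two stay mutually consistent. TKE = ½ ρ Σ σ_e² with ρ = 1060 kg/m³.
  Voxels with |S_e| = 0 receive a configurable σ² cap (default 20·(VENC/π)²)
  and a warning mask instead of +inf.

### Phase-wrap correction

Velocities beyond VENC alias by multiples of 2·VENC. The corrector compares
each masked voxel with the median of its masked 26-neighbourhood and, when
the difference exceeds VENC, adds the multiple of 2·VENC that minimizes it,
iterating to a fixpoint (≤10 passes). Every change is therefore an exact
integer multiple of 2·VENC. This spatial-median scheme is a stand-in: the
field uses several unwrapping strategies (temporal, spatial, Laplacian) and
the choice is not critical at phantom scale.

### Static-tissue detection and background correction

Residual background phase appears as a spatially smooth additive velocity
offset. Static tissue is detected as voxels whose magnitude reaches the 25th
percentile of nonzero magnitudes and whose speed has both temporal SD and
temporal mean below a threshold (default 0.03 m/s; the mean term rejects
steadily moving voxels). The offset is then fitted per timeframe and per
direction by ordinary least squares on the full 3D monomial basis of total
degree ≤ 4 (35 coefficients) in coordinates normalized to [−1, 1] per axis —
normalization keeps the Vandermonde system well conditioned — and subtracted
everywhere. The fit is a linear projection, so applying it twice changes
nothing; the suite checks recovery of a known degree-4 offset to 1e−8. The
correction operates on velocity rather than raw phase; the two differ only
by the constant VENC/π and the velocity form is directly testable.

## Reference-encoding prediction

The learning task is image-to-image translation from the six real/imaginary
motion-encoding channels to the two reference channels, using a 3D U-Net
(configurable depth/width; two 3³ convolutions per resolution level,
optional instance normalization, 2× average-pool down / nearest-neighbour up,
skip concatenation, 1³ output convolution). Two training strategies:

* **adversarial**: the U-Net is the generator of a conditional GAN. The
  discriminator (stacked conv/LeakyReLU/pool blocks emitting a patch-wise
  logit map) sees the six conditioning channels concatenated with real or
  generated reference channels. Generator loss = L1 + BCE-with-logits
  (fake classified as real), summed with unit coefficients by default (both
  exposed, since pix2pix-style frameworks conventionally up-weight L1);
  discriminator loss = the average of its real-as-real and fake-as-fake
  BCE terms.
* **velocity-weighted**: no discriminator. The L1 error is weighted per
  voxel by w = M/p(|v|), where p comes from a speed histogram computed once
  over the training split (99 equal bins on [0, 0.3·VENC) plus one overflow
  bin up to 2 m/s) and M is the reference-encoding magnitude of the target
  image. p is floored at 1/(10·N) so empty bins cannot produce infinite
  weights. Bin assignment uses the 4-point velocities available at training
  time; no weights are needed at inference. Note 0.3·VENC = 0.36 m/s at
  VENC 1.2 m/s; the 0.3·VENC definition is used exactly.

Preprocessing follows the standard recipe: per-encoding magnitude
normalization to [0, 1] (phases untouched) followed by per-timeframe
zero-meaning of every real and imaginary channel. Both statistics are
recorded on the `EncodingSet`. At inference the predicted reference lives in
this preprocessed space, and subtracting a volume mean *changes voxel
phases*, so recombining it naively with preprocessed motion encodings would
distort the velocity map nonlinearly. The package instead un-centralizes the
prediction by adding back the mean of the motion-encoding channel means (a
computable proxy for the unknown reference mean) and reconstructs against
normalized-but-uncentralized motion encodings; the smooth residual this
proxy leaves is removed by the background polynomial fit. This mirrors the
empirical observation that background correction absorbs a large
pre-correction bias in referenceless reconstructions.

Training samples one random timeframe and one uniformly random spatial patch
origin per subject per epoch; optional whole-volume augmentation (per-axis
flips, small rotations ≤10°, isotropic zoom in [0.9, 1.1], each with
probability 0.5 — the probabilities are not dictated by any protocol and are
package defaults) is applied to all eight channels identically before
patching. The optimizer is AdamW; the learning rate is constant for a
configured number of epochs and then decays linearly to zero. Per-fold
models are trained on a subject-level partition and ensembled at inference
by channel-wise averaging. Full volumes that exceed memory are tiled with an
overlap margin; kept tile interiors abut exactly, so when the margin covers
the network's receptive-field radius, tiled and untiled inference agree in
the interior to machine precision.

All of this runs in NumPy with hand-written backward passes (no GPU
framework is assumed); every layer's gradient is verified against central
differences in the test suite. Defaults of `ReferencePredictor` are sized
for CPU toy runs; `TrainConfig` records the full-scale recipe (64×64×32
patches, batch 8, thousands of epochs, 5 folds), which this package does not
attempt to run.

## The phantom: what it emulates and what it does not

The stated world is a whole-heart acquisition at VENC 1.2 m/s, 40
reconstructed timeframes per cardiac cycle and ~2.8 mm isotropic voxels,
desk-scaled to a 32³ grid by default. It contains: two straight tubes along
FH ("aorta", "pulmonary") with parabolic pulsatile profiles (the temporal
waveform is a raised-cosine systolic pulse over the first 40% of the cycle
plus small E/A diastolic bumps, normalized so the configured peak velocity is
attained exactly); a spherical chamber with slow three-directional swirl
(≤0.3 of peak); static tissue (magnitude 0.7 vs 1.0 in blood); a low-signal
lung slab (magnitude 0.03); a jet core carrying per-direction intravoxel SD;
and a background phase that is an exact random polynomial of configured
order in normalized coordinates, modulated smoothly (sinusoidally) over the
cycle. The background's spatial form in vivo is not documented beyond being
smooth with cardiac-cycle evolution; polynomial-in-space/smooth-in-time is
an explicit modelling assumption here.

Not modelled: k-space sampling, coil sensitivities and parallel-imaging
artefacts, concomitant-gradient phase (corrected scanner-side in practice),
respiratory motion, anatomical realism. A green phantom test therefore
establishes internal consistency of the chain (simulation ↔ reconstruction
↔ learning ↔ metrics) and CPU-scale learnability of a simple shared phase —
not clinical performance. Cohort-level error figures cannot be reproduced
without the original patient data and full-scale GPU training, and the
package does not attempt to.

## Agreement metrics

Voxel-wise ordinary least squares of test on reference per direction (and
optionally per timeframe) with Pearson r and RMSE; Bland-Altman bias and
limits of agreement reported as the single 1.96·SD half-width. Differences
are test − reference, so negative bias means the referenceless arm
underestimates. Per-beat flow volume through a one-voxel-thick plane is
Q = Σ_t Σ_vox v_normal·A·dt in mL. Peak systole is the systolic frame
(first 40% of the cycle) maximizing mean aortic speed; summaries average
velocity/TKE over a 4-frame window centred on it (a centred window is a
choice; a leading window would shift summaries by at most one frame), then
report region mean/max speed, volume-integrated TKE in mJ and maximum TKE
in J/m³. Tidy CSV output, one row per subject × timeframe × direction, plus
median/IQR roll-ups.

## Known limitations

* The velocity-weighted loss deliberately de-emphasizes the image
  background, so whole-image dev MAE can rise while blood-velocity agreement
  improves; the adversarial mode optimizes L1 directly and its dev MAE
  decreases monotonically at toy scale. Model selection for the weighted
  mode should therefore use a weighted or blood-masked metric.
* The σ² estimator's factor-of-two ambiguity is resolved by internal
  consistency, not by adjudicating the literature; both conventions are one
  flag apart.
* The spatial-median unwrapping is a stand-in and untested against extreme
  aliasing (multiple wraps in large connected regions).
* Protocol arithmetic assumes all encodings of a timeframe are interleaved
  within the cardiac cycle and scan time ∝ lines/segmentation factor; it
  ignores navigator efficiency and heart-rate variability.
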