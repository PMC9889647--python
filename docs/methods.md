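# Methods

`leafseq` predicts deliverable step-and-shoot IMRT field segments — MLC
aperture shapes plus monitor-unit (MU) weights — directly from a per-beam
target dose distribution, using a conditional GAN, and closes the loop by
converting predictions to MLC control points, recomputing dose, and
scoring the replan with gamma analysis and DVH comparison.  Because no
clinical dataset or commercial treatment-planning system is available to
this package, a synthetic plan/dose simulator defines the study
conditions end to end.  This note records the model, the simulator, the
numerical choices, and what the tests do and do not establish.

## The learning problem

A step-and-shoot beam delivers an ordered set of field segments; each
segment is a static MLC aperture with an MU weight.  Viewed from the
beam's eye view (BEV), the MU-weighted sum of a beam's apertures closely
resembles the 2D projection of the dose that beam deposits.  The package
therefore frames leaf sequencing as image-to-image translation:

* **input** `x`: the beam's 3D dose, shifted so the isocenter sits at the
  rotation centre, rotated to the BEV, summed along the beam axis,
  resampled to the fixed 128 x 128 full-field raster and rescaled to
  [0, 1] (the removed maximum is kept as `scale` sidecar metadata);
* **target** `y`: a [128, 128, 6] stack in which channel *c* holds the
  *c*-th segment's binary aperture mask times its MU normalized by the
  plan's largest segment MU (`mu_scale`, also carried as sidecar);
  beams with fewer than six segments are zero-padded.

Both images live on the same machine raster — rows along the linac X
axis (80 leaf rows x 7.15 mm = 572 mm), columns along the linac Y
leaf-travel axis (220 mm), centred on the isocenter — so the network can
learn the spatial correspondence directly.  The package verifies the
premise quantitatively: on a 64 cubed, 3 mm grid the normalized BEV dose
projection and the MU-weighted channel sum correlate at a cohort-mean
Pearson r of about 0.97 (asserted >= 0.95 in the suite).

## Model

The generator is a U-Net: six down-sampling blocks (4 x 4 convolution,
stride 2, batch normalization except on the first block, leaky ReLU 0.2),
mirrored transposed-convolution up-sampling blocks (batch normalization,
ReLU) with skip connections, dropout (default 0.5) on the three
innermost up blocks as the stochasticity source, and a linear 6-channel
output head.  The discriminator is a 70 x 70 PatchGAN over the
concatenated (dose map, aperture stack) pair, with spectral normalization
(one power iteration per step; gradients treat the singular vectors as
constants) on every convolution; it emits a grid of patch logits rather
than a scalar.

The discriminator minimizes binary cross-entropy against *soft labels*
(real ~ U[0.8, 1.2], fake ~ U[0, 0.2], both sub-ranges configurable)
with a 5% per-sample chance of label flipping.  The generator minimizes
the adversarial cross-entropy plus `lambda_l1` (default 100) times the
mean absolute error to the ground-truth stack.  Optimization is Adam
with `beta_1 = 0.5`; per batch, both networks' gradients are taken
through the same discriminator forward passes and then applied one
network at a time (the usual simultaneous scheme).  Sources differ on the learning rate for this
protocol (both 1e-3 and 1e-4 appear); the package defaults to 2e-4, the
value standard for this architecture family, and both alternatives are
one `TrainConfig` field away.  Batch size defaults to 1; batch statistics
are used in normalization at both train and inference time, which at
batch size 1 behaves like instance normalization and makes inference
deterministic.  Dropout is disabled at inference.

The entire network — convolutions via im2col and BLAS matmul, manual
backpropagation, Adam, spectral norm — is implemented in numpy in
`cgan.py`.  Gradients of every layer are validated against finite
differences in the suite, and a memorization oracle (10 training pairs,
small model) must reach per-pixel MAE < 0.05.

## Cohort structure and cross-validation

The simulated study follows a 10-patient cohort, five fractionated plans
per patient, 11 beams per plan at the fixed gantry set (5, 25, 60, 90,
155, 175, 195, 260, 290, 310, 345 degrees): 50 plans and 550 per-beam
training samples.  Validation is patient-based leave-one-out with a
twist: exactly one fraction (fraction 1, the "prior plan") of the
held-out patient stays in training, so each fold trains on 9 full
patients + 1 prior fraction and tests on the remaining four fractions —
44 held-out beams per fold.

## The synthetic simulator

The simulator is first-class, tested code; its defaults are the study
conditions.

* **Phantom**: ellipsoidal body on a 96 cubed, 3 mm grid (default); an
  ellipsoidal PTV (12-22 mm semi-axes) near the grid centre; five OAR
  masks chosen to exercise DVH comparisons — a C-shaped duodenum-like
  annulus abutting the PTV, two lateral kidney-like ellipsoids, a
  posterior cord-like cylinder, an anterior stomach-like blob.  OARs
  exclude the PTV by construction.
* **Apertures**: per beam, 1-6 segments (the model's channel count caps
  the simulator default at six even though clinical plans can reach 12;
  preprocessing offers an error-or-merge policy for larger beams).  Each
  aperture is a randomly perturbed ellipse conformal to the PTV's BEV
  projection, built row by row with edge travel clamped to two leaf
  widths so apertures are connected and smooth.  MU weights are
  log-uniform over [20, 200] MU — no published distribution exists, so
  this range was declared once as a plausible clinical spread.
* **Dose engine**: an idealized attenuated back-projection.  Fluence is
  the MU-weighted sum of binary aperture masks rasterized at 2 mm and
  blurred with an isotropic Gaussian penumbra (sigma = 3 mm, a soft
  tissue-like default).  Rays are parallel along the beam axis;
  attenuation is exponential over the water-equivalent depth inside the
  body (mu = 0.005/mm); per-beam dose is rotated about the isocenter by
  the gantry angle and summed over beams.  The engine is exactly linear
  in MU and fully deterministic, and the same engine recomputes
  predicted-plan dose, so all comparisons are internally consistent.
  It replaces the clinical Monte Carlo dose engine that produced the
  original data; no scatter, heterogeneity, divergence, MLC transmission
  or tongue-and-groove effects are modelled.

What passing tests therefore show: the full method — preprocessing,
training, sequencing, evaluation — is self-consistent and learns the
dose-to-segments mapping under idealized physics with conformal,
connected apertures.  What they do not show: performance on clinical
dose distributions, real MLC deliverability margins, or the published
clinical gamma rates, which belong to data this package cannot access.

## Leaf sequencing

Per predicted channel: values below 2% of the prediction's maximum
intensity (the stack maximum) are zeroed; the MU is the channel maximum
(de-normalized by `mu_scale`) and every surviving pixel is forced to it.
Referencing the threshold to the stack maximum rather than each
channel's own peak matters: zero-padded channels predicted as low-level
noise then empty out and are dropped, whereas a channel-relative
threshold would keep their specks (relative to their own tiny peak),
bridge them into large spurious apertures, and deliver several times the
intended dose; the image rows are grouped onto
the 80 leaf rows and each leaf row opens from the leading edge of its
first open pixel to the trailing edge of its last.  Pixel centres decide
openness and pixel edges decide leaf positions, which makes
rasterize -> extract -> rasterize a projection pair: on binary
ground-truth stacks the round trip is bitwise and MUs are recovered
exactly (asserted in the suite).  Interior holes in a row are bridged —
one leaf pair cannot form two openings; this is the conservative reading
of edge detection along the two axes.  Diaphragms close to the bounding
box of open rows.  Channels that are empty after thresholding are
dropped; a beam that loses all channels raises an error, because a
replan must not silently lose a beam.  Emitted positions are quantised
to 0.1 mm, which is below half a raster pixel and therefore preserves
the round trip.

## Evaluation

* **Gamma**: per reference voxel, the minimum over a search
  neighbourhood of sqrt(dose term + distance term), 3%/3 mm with a 5%
  low-dose threshold, global normalization to the reference maximum by
  default (local available).  The search lattice is trilinear with
  1/`subsample` voxel steps (default 10) within three times the DTA.
  The production search (numba) visits offsets sorted by distance and
  stops per voxel once the distance term alone exceeds the running
  minimum, optionally capped at `max_gamma` (pass/fail stays exact for
  caps >= 1; capped values are lower bounds).  A deliberately exhaustive
  brute-force implementation over the identical lattice is the
  correctness oracle; the suite checks per-voxel agreement to 1e-6
  across seeds and criteria.  Gamma is asymmetric; the reference is
  always the ground-truth dose.
* **DVH**: cumulative histograms in 1 cGy bins per ROI; Dmax, Dmean and
  V(d) summaries.  Percent differences are 100 x (truth - predicted) /
  truth, negative when the prediction runs hot, averaged across the four
  held-out fractions.
* **Reports**: per fold, a per-fraction gamma pass-rate table and a
  per-ROI max/mean dose percent-difference table, as CSV with a
  provenance header (package version, config hash).

## Scaled-down study sizes

Full-scale training (550 beams at 128 x 128 for 200 epochs) is a
multi-hour numpy run, so the self-contained learning check runs at
reduced scale, chosen once: a 6-patient x 5-fraction cohort on a
48 cubed, 4 mm grid; 64 x 64 images; 16 base filters; 40 epochs; one
leave-one-out fold.  The check is directional: sequenced plans from the
trained model must beat an untrained (randomly initialized) model's mean
gamma pass rate by at least 30 percentage points on the held-out
fractions.

Adversarial training oscillates — the sequenced dose amplitude of a
snapshot can swing by factors of 2-4 between epochs even while the L1
loss stays flat, because low-level energy in zero-padded channels is
invisible to the mean but becomes a deliverable segment once the MU is
read off the channel maximum.  The training loop therefore realizes
"train until stable" as snapshot selection: every two epochs the
generator is scored by *delivery fidelity* — the mean absolute error
between the sequenced fluence (threshold, force-to-max) of its
predictions and the ground-truth fluence on a fixed subset of training
beams — and the best-scoring snapshot is the model returned.  The score
never sees held-out data.  Snapshots are taken from an exponential
moving average of the generator weights (decay 0.9995, a horizon of
roughly seven epochs at this training-set size), which integrates over
the adversarial oscillation instead of sampling it; selection then picks
among already-smoothed models.  One caveat this metric targets directly: the
synthetic apertures of one beam are all conformal to the same PTV
projection, so the per-channel decomposition of a dose map is only
weakly identifiable (several channel splits explain the same dose);
clinical segments are more complementary in shape, which makes the
clinical task better conditioned at the channel level than the
simulated one.  Pipeline-level gamma uses `subsample = 5` and
`max_gamma = 1.1` (search fineness 0.6-0.8 mm against a 3 mm DTA;
capped values only affect failing voxels' reported magnitudes, never
pass/fail).

## Degenerate inputs and tie-breaks

All-zero dose maps normalize to zero with `scale = 0` flagged; all-zero
channels signal "empty segment"; a target radius of zero opens a single
minimal leaf row; rotations and shifts use trilinear interpolation with
true zero padding (`grid-constant`), exact for 90-degree multiples and
integer-voxel shifts; DICOM leaf/jaw positions are DS strings quantised
to 0.1 mm; RTDose stores Gy as scaled 32-bit integers (internal unit is
cGy) with quantisation at reference-max / (2^31 - 1).

## Known limitations

Idealized physics (see above); channel order must match delivery order
for the zero-padding convention to be learnable; the 6-channel cap drops
or merges information for busier beams; no interdigitation or overtravel
constraints are enforced beyond leaves-within-field; the GAN equilibrium
heuristic (generator loss roughly equal to discriminator loss) is logged
but not used as a stopping rule — training runs a fixed epoch budget.
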