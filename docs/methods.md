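# Methods

`fedseg3d` simulates privacy-preserving federated training of a 3D
segmentation network across four institutions, end to end on one CPU. This
note documents the models and procedures it implements, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not show.

## Problem setting

Four clients (institutions) hold disjoint, unequally sized shards of
glioma-like imaging cases — four MRI contrast channels (T1, T1Gd, T2,
FLAIR) plus an expert-style label map over {0, 1, 2, 4} (necrotic/
non-enhancing core = 1, peritumoral edema = 2, enhancing tumor = 4). The
model is trained to predict the three nested evaluation regions directly:

* **ET** (enhancing tumor) = label 4,
* **TC** (tumor core) = labels {1, 4},
* **WT** (whole tumor) = labels {1, 2, 4},

the standard region composition for this annotation scheme. A server
coordinates rounds: broadcast global weights → local training → aggregate.
No raw data ever leaves a client; privacy is additionally hardened by
noise perturbation and by sharing only a random fraction of weights.

## Synthetic phantoms

Real multi-institutional MRI cannot ship with a test suite, so every stage
runs on generated phantoms: an axis-aligned brain ellipsoid of nonzero
intensities on an exactly-zero background, with three concentric tumor
spheres (ET ⊂ TC ⊂ WT by construction — the smallest geometry that
guarantees the nested-region structure the loss and metrics assume).
Each (modality, tissue) pair has a configurable mean intensity with
Gaussian noise (sd 0.05 by default); the default contrast table gives each
channel a distinct tissue ordering (enhancing tumor brightest on T1Gd,
edema on FLAIR/T2) so channel-level operations are observable. Tumor
position and radii vary per case; voxel spacing defaults to 1 mm isotropic
so HD95 is reported in millimetres.

What the phantoms do **not** emulate: anatomical texture, irregular tumor
shapes, site-specific intensity distributions, imaging artifacts. Passing
tests therefore demonstrate the correctness of the pipeline's mechanics
(preprocessing, loss, aggregation rules, scheduling, evaluation geometry)
and the qualitative behavior of federation — not clinical segmentation
performance.

## Preprocessing and augmentation

Per channel and per case: intensities are clipped to the 1st/99th
percentiles of the *nonzero* voxels (linear-interpolation percentiles),
then min–max scaled using the post-clip channel min/max — zeros included —
so the background maps exactly to 0, which the brain-bounding-box step
relies on. Volumes are cropped to the tightest box containing the brain,
then randomly re-cropped to the training patch size (symmetric zero
padding when the brain is smaller than the patch). All boxes are 0-based
and half-open.

Training-time augmentation applies, in a fixed order for replayability:
per-channel rescale by one factor ~ U(0.9, 1.1) with p = 0.8; per-channel
shift ~ U(−0.1, 0.1) with p = 0.1; additive Gaussian voxel noise of sd 0.1
(applied unconditionally by default, exposed as `noise_p`); channel
dropping with p = 0.16; and independent per-axis flips with p = 0.8,
applied identically to the labels. Rescale/shift draw one scalar per
channel — the channel is the unit of those transforms; a per-voxel draw
would be indistinguishable from the noise transform. Each client derives
its own augmentation stream from the run seed, so clients see distinct
randomness.

## Network and loss

The network is a conventional 3D U-Net: encoder stages of two 3×3×3
convolutions with group normalization (batch-size independent — training
uses batch 1) and ReLU, 2× max pooling, filter counts doubling per stage;
a mirrored decoder with 2×2×2 transposed-convolution upsampling and skip
concatenation; and a final 1×1×1 convolution with sigmoid emitting one
probability map per region. Depth and width are configurable; the `tiny`
preset (depth 2, 4 base filters, ≈22k parameters) is the CPU-scale
default; weights initialize he-normal from a seed.

The engine is written in numpy with hand-derived backward passes; the
3×3×3 convolutions run as compiled (numba) direct-convolution kernels, and
every layer's gradient is verified in the test suite against float64
brute-force oracles or finite differences. Compute is float32: at these
parameter counts memory traffic, not arithmetic, dominates.

The loss is soft Dice accumulated per channel over the batch:

    L = 1 − (1/N) Σ_n (2 Σ S_n R_n + ε) / (Σ S_n² + Σ R_n² + ε),  ε = 1.

A `verbatim` variant omitting the factor 2 in the numerator is provided
for comparison; that form cannot reach 0 for a perfect prediction (an
all-ones 8-voxel channel evaluates to 1 − 9/17) and is not used for
training. Optimization is Adam, learning rate 1e-4 at full scale.

## Federation engine

Plain **full** mode is classic federated averaging: after E = 3 local
epochs the server replaces the global weights with the sample-size-
weighted mean Σ (n_k/n) w_k over the round's participants.

**Partial** mode is the privacy-preserving variant: each client draws a
sharing fraction q ~ U(0.4, 0.5) each round and a per-layer uniform random
position mask (round-half-away-from-zero of q·count positions, minimum one
per layer so every layer contributes); non-selected weights are
transmitted as zeros. The server then applies, per weight position:

1. all clients zero → keep the previous global value;
2. exactly one nonzero → take that client's value;
3. two or more nonzero → unweighted mean of the nonzero values;

and finally averages elementwise with the previous global model,
`w_global ← (w_prev + w_new)/2`. Rule 3 uses an unweighted mean by
design (an n_k-weighted aggregation is what full mode provides). The
protocol cannot distinguish a trained weight that is exactly zero from a
masked one; for continuous weights this is a probability-zero event and is
documented as inherent.

Differential-privacy perturbation is Gaussian (the distribution is a
configurable choice): applied once to each client's training volumes
before training (sd 1e-2) and to each local weight update after training,
before masking/transmission (sd 1e-3). Both scales are free parameters.

Client dropout emulates institutions going offline: within a configured
epoch window (default epochs 50–150, period 10), rounds whose starting
epoch falls on the period exclude one uniformly chosen client from both
training and aggregation. Rounds are indexed by starting global epoch
(round r starts at epoch rE + 1), which makes the window and the
"validate from epoch 9" rule executable; validation of the global model
runs once per round from that epoch on. Optimizer state is client-local
and resets each round — only weights are federated state.

## Two-step validation

During training (step 1), fixed-size validation patches are scored with
the training loss and per-region Dice of the 0.5-thresholded predictions.
After training (step 2), each validation case is processed whole: crop to
brain extent, zero-pad, predict, unpad, threshold at 0.5, reconstruct a
{0, 1, 2, 4} label map by boolean operations (with nesting repair
TC := TC ∨ ET, WT := WT ∨ TC so inconsistent voxels resolve
deterministically), and score per region: DSC, sensitivity, specificity,
and HD95.

HD95 is the 95th percentile (linear interpolation) of the pooled
bidirectional surface-distance set; surfaces are 6-connected face
boundaries with the array border counting as background. The pooled
estimator (vs the max of directed percentiles, available via a flag) is
symmetric and matches common evaluation tooling. Conventions for empty
masks: both empty → DSC 1, HD95 0; prediction-only or truth-only empty →
HD95 undefined (NaN, excluded from means with a warning); sensitivity/
specificity fall back to 1 when their denominator is empty.

One numerical subtlety found during development: a network trained on
fixed-size patches is sensitive to the zero-border fraction of its input
through the group-norm statistics. Whole-image inference therefore pads
the cropped brain to the training patch size (not merely to the pooling
multiple) in the desk-scale experiment, keeping training and inference
input distributions matched.

## Desk-scale experiment

The headline computation (`fedseg3d.experiments.run_desk_scale_experiment`,
also behind `scripts/acceptance.py`) scales the full study down to one
CPU: 34 phantoms at 32³ split 24/8/2, four clients sharded by largest-
remainder apportionment of 37:50:80:100 (→ 3/5/7/9 cases), the tiny
network, 30 rounds × 3 epochs (= 90 epochs for the centralized baseline),
default DP noise and dropout window, whole-image evaluation on the 8
held-out validation phantoms. Learning rate is 1e-2 at this scale: with
≈22k parameters and ≈2000 optimizer steps, the full-scale 1e-4 leaves the
small ET/TC structures unlearned within the budget, while 1e-2 trains all
three regions in every mode; this is a property of the reduced problem
size, and the full-scale default remains 1e-4.

Typical behavior (seed 1): centralized whole-image WT Dice ≈ 0.97,
full-federated ≈ 0.91, partial-federated ≈ 0.92, with federated modes
converging more slowly than the centralized baseline and partial mode
slowest — the qualitative ordering expected when averaging, masking and
noise are layered onto training. Run-to-run spread at this cohort size is
a few points of Dice.

## Known limitations

* Phantom simplicity bounds what the experiments can claim (see above).
* Single-sample training only; gradient accumulation stands in for larger
  batches.
* The federation is simulated in-process and sequential; no real
  networking, stragglers, or asynchrony.
* No encryption, secure aggregation, or formal (ε, δ) accounting — the DP
  mechanism is plain noise perturbation with unquantified guarantees.
* The `full-scale` model preset reproduces the architecture family at
  full width but is not trainable at desk scale and ships untested beyond
  construction.
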