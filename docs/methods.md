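# Methods

## Problem and model

The package studies paired image-to-image translation between two clinical
views of the diabetic macula: mid-phase fluorescein angiography (FA)
frames, and OCT 3-D macular reports whose color-coded square encodes
retinal thickness (ILM to RPE-junction) on a 0–500 µm scale. The two
modalities are linked by pathophysiology — vascular leakage visible as
hyperfluorescent halos on FA co-occurs spatially with macular thickening
on the OCT map — and the translator's job is to learn exactly that
conditional dependence.

The translator is a pix2pix conditional GAN. The generator G is a U-Net:
stride-2 4×4 convolutions halving resolution down to a 1×1 bottleneck,
mirrored by stride-2 transposed convolutions, with skip connections
joining equal resolutions; the output layer is a tanh, so translations
live in a bounded symmetric range and are mapped affinely to 8-bit. The
discriminator D is a PatchGAN scoring overlapping patches of the
(source, candidate) channel concatenation: three stride-2 convolutions
plus two stride-1 heads, which yields the classic 30×30 score grid at
256 px input (70×70 receptive field per patch). The objective is

    L_D = ½·[BCE(D(x, y), 1) + BCE(D(x, G(x)), 0)]
    L_G = BCE(D(x, G(x)), 1) + λ·E‖G(x) − y‖₁ ,   λ = 100

with binary cross-entropy on patch logits and the mean absolute pixel
difference as L1. λ = 100 makes reconstruction dominate; λ is exposed and
the suite checks directionally that dropping it (λ = 0) does not lower
reconstruction error. Optimization is Adam (lr 2·10⁻⁴, β₁ 0.5), batch
size 1. The generator is snapshotted every `checkpoint_interval_epochs`
epochs (default 10) over `epochs` (default 200), i.e. 20 checkpoints per
direction at the defaults; two independent models cover the FA→OCT and
OCT→FA directions.

Everything runs on numpy with hand-derived backprop (im2col convolutions,
instance normalization, leaky ReLU/tanh); layers were verified against
central-difference gradients in float64. Two deliberate departures from
the original pix2pix recipe, both in the service of a strict determinism
contract on a single CPU thread: decoder dropout (pix2pix's noise source)
is omitted, and batch-size-1 batch normalization is realized as instance
normalization — equivalent at batch 1 and free of train/inference
statistics drift, so `translate()` is a pure function of (weights, input).

## Checkpoint selection

Each saved generator translates the held-out sources; real targets and
syntheses are embedded, each set is fitted with a Gaussian (sample mean,
unbiased covariance), and the Fréchet distance

    FID = ‖μ_r − μ_s‖² + Tr(Σ_r + Σ_s − 2(Σ_r Σ_s)^{1/2})

is evaluated with the cross term computed on the positive-semidefinite
symmetrization Σ_r^{1/2} Σ_s Σ_r^{1/2} (same trace as (Σ_r Σ_s)^{1/2});
eigenvalues below −10⁻⁶ of the spectral radius raise, smaller negatives
clamp to zero. The argmin checkpoint wins; ties break toward the earliest
epoch, since training past the optimum risks overlearning. The embedding
is pluggable. The default desk extractor — resize to 32×32 grayscale,
flatten, project through a fixed seeded Gaussian matrix to 64 dimensions —
is deterministic and exercises every FID code path; absolute FID values
are therefore on the desk extractor's scale, not comparable to
inception-based numbers.

## Evaluation metrics

All four paired metrics treat images as 8-bit, converting RGB to gray via
BT.601 luma weights (0.299, 0.587, 0.114) where needed.

- **PSNR** = 10·log10(255²/MSE), in dB; MSE = 0 maps to a +inf sentinel
  which aggregates exclude (with a reported count).
- **SSIM**: Gaussian-windowed (11 taps, σ 1.5) local luminance–contrast–
  structure product with stabilizers (0.01·255)² and (0.03·255)² — the
  field-standard parameterization; a window-radius border is cropped
  before averaging. Agrees with an independent reference implementation
  to 1e-6 on phantom pairs.
- **Hamming distance**: 64-bit average hash (exact fractional-area
  8×8 downscale in float, bit = strictly above the 64-pixel mean,
  row-major). Raw distance feeds the interpretation bands (0 similar,
  1–10 potential variation, >10 likely different); aggregates use
  raw/64, and report headers state which is which. The float downscale
  (rather than a rounded uint8 resize) is what makes the hash exactly
  invariant under brightness shifts that preserve the above-mean set.
- **LPIPS-style feature distance**: activations of a convolutional
  backbone are unit-normalized per spatial site; squared differences are
  averaged within each layer and summed across layers; per-pixel layer
  sums upsampled to input size give the distance map. The default desk
  backbone is a fixed 3-layer conv stack with seeded weights — untrained
  convolutional features are known to rank perceptual similarity far
  better than pixel metrics, which licenses a weight-seeded default; a
  pretrained classification backbone plugs in through the same
  interface. Layer weights are 1.

## Phantoms: what they emulate and what they do not

Clinical archives of co-registered FA/OCT pairs are private, so the
phantom module generates the study data. A phantom pair shares one
coordinate frame: a thickness field (250 µm baseline plus Gaussian edema
bumps of 50–250 µm at microaneurysm sites, plus a smooth seeded noise
floor) is rendered twice — once as an OCT report (gray fundus with a
cosmetic vessel tree, the color-coded square centered on the fovea, a
color bar on the right margin) and once as an FA frame (bright perfused
background, bright vessel tree excluded from the avascular zone, dark FAZ
disc at the fovea, bright microaneurysm dots, leakage halos per grade).
Halo centers equal edema centers exactly; that co-location is the
learnable signal. ETDRS-style grades map to microaneurysm counts and
leakage modes (none for no-DR/mild, focal for moderate/severe, diffuse
for PDR); with no leakage there is no edema. Fovea jitter is ±canvas/16
so the colored square always stays inside the central scan window; the
square's half-side is canvas/8. Left eyes are exact mirrors of the
right-eye geometry, making the mirroring stage exactly invertible. The
FAZ darkening is drawn after the leakage halos — mid-phase frames are
chosen clinically precisely because dye pooling has not yet masked the
FAZ — so the avascular zone stays dark and symmetric at every grade.

The color scale is a piecewise-linear table with stops at 0 violet,
100 blue, 225 green, 300 yellow, 350 orange, 425 red, 500 white (the
device's true breakpoints are proprietary; these are configurable, and
only the ordering matters downstream). Decoding inverts by nearest color
over a 1 µm lookup table; the overlay is opaque by default (alpha
exposed) so render→decode recovers the field within one quantization
step everywhere inside the square.

Phantoms deliberately do not model: photorealistic fundus texture, dye
transit phases, cystoid/serous edema morphology, media opacity, device
quality scores, or segmentation-hostile artifacts (dark frame outlines,
eccentric fixation). Passing tests therefore show that the pipeline's
mechanics — co-registration, training dynamics, selection, metrics — are
correct and internally consistent, not that clinical-grade translation
quality is achieved; the clinical headline numbers depend on private data
and full-scale GPU training and are out of scope here.

The three virtual-FA diagrams place microaneurysm dots on concentric
rings of constant radial increment (6k dots on ring k, staggered) around
a central FAZ, with no halos / focal halos / diffuse confluent halos.
When fed to the trained FA→OCT generator, ring layouts are confined to
the region a fovea-centered crop keeps, so the diagram matches the
training-crop geometry; the dose-response check decodes the synthesized
maps through the color scale and expects higher mean thickness for
diffuse leakage than for the no-leakage diagram.

## Preprocessing choices

Coordinates are 0-based, x = column, rectangles half-open. The OCT scan
window is the central square of half the report dimension (excluding the
color bar); the FA window is the same size shifted 10% of width leftward.
A pixel is "colored" when max(R,G,B) − min(R,G,B) > 30; the tight bbox of
colored pixels is the thickness square and its midpoint the presumed
fovea. FAZ segmentation thresholds the windowed grayscale: the default
policy is a three-class Otsu taking the lowest cut — with bright leakage
present the window histogram is trimodal and plain two-class Otsu cuts
between background and halo, swallowing the FAZ into the background (on
phantoms this produced centroid errors up to ~85 px; the multi-class cut
brings them below 0.2 px) — with a two-class fallback for degenerate
histograms and a fixed-value policy selectable. The largest dark
component wins (ties to smallest bbox top-left); the centroid comes from
the filled component's first-order moments. Crops overrunning the frame
are padded by edge replication, keeping the fovea centered. The
magnification scale (FA px per OCT px) defaults to 1.0, correct for
phantoms which share one coordinate frame; for real data it is a
required configuration value. Samples whose segmentation fails route to
a manual-review list rather than aborting, mirroring a manual-correction
workflow. JPEG writes use quality 95; every bit-exactness contract is
stated on lossless PNG.

The stratified split gives the test set per-grade quotas of
n_test // n_grades each, spreading the remainder one per stratum
(seeded); if a stratum cannot fill its quota the split falls back to
proportional rounding with a warning. At the full-scale sizes (1195
samples, 110 test) this yields exactly 22 per grade and 1085 training
pairs.

## Problem sizes and numerical choices

The desk-scale study conditions used by the test suite are: 32×32
translator inputs, 150 training pairs (20 held out), 20 epochs with
checkpoints every 2, generator/discriminator base width 16, phantom
canvas 128 px (256 px for the co-registration suite, 50 phantoms). The
contract-quantity script exercises the default 200-epoch / interval-10
schedule with a width-8 model on 4 pairs. These sizes are the package's
chosen desk profile: large enough for the learning signal (held-out SSIM
of translations exceeds the source-vs-target baseline; FID of the
selected checkpoint not worse than the first) while keeping every run a
few minutes on one CPU core.

Numerical notes: training arithmetic is float32 (metrics and FID in
float64); weight init is N(0, 0.02²) from per-component seeded streams;
data order reshuffles per epoch from the same seed stream, so identical
(pairs, config) runs are bit-reproducible on a single thread. FID
checkpoint ties break early; argmin over an epoch-sorted curve makes
selection invariant to checkpoint ordering. SSIM requires images at
least as large as its window (11 px). Degenerate inputs raise typed
errors (`ParameterError`, `NoFAZFound`, `NoColorMapFound`,
`StatsUndefined`, `NumericalError`) rather than propagating NaNs.

## Known limitations

- The numpy translator is single-threaded CPU code; full 512 px / 200
  epoch training is expressible (the paper-scale profile) but slow — the
  desk profile is the supported regime.
- Phantom realism is intentionally minimal (see above); absolute metric
  and FID values are not comparable to values computed on clinical data
  or with pretrained embeddings.
- The desk FID extractor and desk LPIPS backbone are fixed random
  projections/filters: excellent for contract testing, weaker as
  perceptual judges than pretrained networks, which can be plugged in.
- Vessel-based multimodal registration is out of scope by design: the
  color overlay obscures the underlying vasculature, which is why the
  pipeline registers on the FAZ/square centers instead.
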