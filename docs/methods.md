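# Methods

`finholo` implements a complete desk-scale stack for lensfree in-line
holographic microscopy of thin transmissive specimens: the acquisition
physics, the classical reconstruction chain (pixel super-resolution,
autofocusing, iterative multi-height phase retrieval), and a learned
end-to-end reconstructor (FIN, a Fourier Imager Network built from
spectral SPAF modules) together with its training loop and evaluation
metrics.  This note records the models, the parameters that matter, and the
design decisions taken where the design was genuinely open.

## Imaging model

A monochromatic plane wave (wavelength λ, default 0.530 μm) illuminates a
thin specimen modeled as a multiplicative complex transmittance
t(x, y) = A·exp(iφ), |A| ≤ 1.  The field then propagates a sample-to-sensor
distance z₂ ∈ [300, 600] μm in air and the sensor records intensity only;
the lost phase is what every reconstruction method here recovers.

Propagation uses the angular spectrum method: multiply the field's 2D DFT by
H(fx, fy) = exp(i·2π·z·√((n/λ)² − fx² − fy²)) on propagating frequencies.
Conventions, fixed once and used everywhere (simulator, MH-PR, SPAF, loss):

* forward DFT with negative exponent and no scaling; inverse carries 1/N²
  (numpy's default);
* frequency samples at the standard DFT spacing 1/(N·pitch), DC at index 0;
  spectra are centered (fftshift) only for display and for the SPAF windows;
* evanescent frequencies are hard-zeroed.  At the distances used (≥300 μm)
  any evanescent content is attenuated by factors beyond e^(−1000), so the
  choice is numerically irrelevant, and zeroing cannot overflow for either
  propagation direction.  z = 0 is special-cased to the exact identity.
* no zero-padding by default — the synthetic world is genuinely periodic, so
  wrap-around is self-consistent; `propagate(..., pad=True)` pads to the
  next power of two for compact-support fields on open domains.

Degenerate inputs (non-positive pitch or wavelength, sub-2×2 grids,
non-finite values) raise `ValueError` at construction.

## Synthetic specimens

Two phantom families emulate the broad structural classes such microscopes
image, with defaults chosen as a single fixed set of study conditions:

* **connected_tissue** — stationary textured fields standing in for stained
  histopathology sections.  Gaussian-filtered white noise (two independent
  draws for amplitude and phase) is mapped through a logistic squashing into
  amplitude ∈ [0.75, 1.0] and phase ∈ [0, 0.8] rad.  The filter width is set
  so the 1/e half-width of the autocorrelation equals the requested
  correlation length (default 5 μm, the scale of sub-cellular texture at a
  0.37 μm pixel).  The 0.8 rad peak phase is at the low end of what a few-μm
  section with Δn ≈ 0.05 produces at 530 nm — strong enough that phase
  matters, weak enough that the thin-object approximation is comfortable.
* **sparse_cells** — isolated smooth super-Gaussian blobs (radius ≈ 8 μm,
  density 500 mm⁻², at least one per field) on a unit background, standing
  in for smear-type slides.  Same amplitude/phase ranges, applied at the
  blobs only.

What these phantoms do **not** model: real histological morphology,
multiple scattering, sample thickness beyond the multiplicative
approximation, partially coherent illumination, or the sensor's color
filter array (an RGB sensor is treated as monochrome at 530 nm —
whether a real pipeline demosaics first is an acquisition detail outside
this package).  Tests passing on these phantoms show the algorithms are
correct and well-conditioned on their assumptions; they do not certify
performance on patient material.

The sensor model applies, in order: optional Poisson shot noise scaled by a
photon budget (default 10⁴ photons per unit-intensity pixel, ~1% relative
noise), optional Gaussian read noise, optional box-integration downsampling
by an integer factor, and optional quantization (12-bit default when
enabled, full scale at twice the mean intensity).  Noise and quantization
are off by default so that definitional identities hold exactly in unit
tests; "realism" experiments switch shot noise and 12-bit quantization on.

## Pixel super-resolution

The 6×6 sub-pixel acquisition raster is simulated by Fourier-shifting the
high-resolution intensity (exact for band-limited signals) before box
integration; shifts are defined as the displacement of scene content in the
captured frame, in low-res pixel units.  Shift estimation uses phase
correlation with local Fourier upsampling (resolution 1/upsample px,
default 0.01 px).  Shift-and-add places every low-res sample at its shifted
position on the fine grid — nearest-fine-pixel binning by default, bilinear
splatting behind a flag — normalizes by per-pixel counts, accounts for the
(q−1)/2 box-integration centroid offset, and fills never-visited fine
pixels by nearest-neighbour interpolation (flagged in a validity mask).
Merging a 2.24 μm sensor at factor 6 yields the 0.373 μm effective pixel
used throughout.  Images remain intensities end to end; amplitudes (square
roots) are taken only where phase retrieval begins.

## Autofocusing

The sample-to-sensor distance is estimated per hologram by back-propagating
the square-root intensity over a coarse distance grid and scoring each
amplitude image with the Tamura coefficient of its gradient magnitude,
ToG = √(std(|∇I|)/mean(|∇I|)) — an edge-sparsity measure that peaks at
focus for absorbing objects.  The coarse argmax (default 5 μm step over
300–600 μm) is refined by bounded golden-section search within one step on
either side.  ToG is invariant to global intensity rescaling up to a
monotone transform, so the argmax is exposure-independent.  For phase-only
objects some criteria dip rather than peak at focus; `mode="min"` selects
that convention.  The score landscape is only well-peaked for objects with
genuine edges: on very smooth textures (our tissue phantom at small fields
of view) the criterion can prefer a spurious distance, which is a known
property of sharpness-based autofocusing, not an implementation artifact.

## Multi-height phase retrieval (MH-PR)

The classical solver cycles through the M hologram planes in ascending
distance order.  For each plane: propagate the sample-plane estimate to the
plane, replace the amplitude with the average (|propagated| + measured)/2
while keeping the propagated phase, and propagate back.  One full iteration
uses all planes; the loop stops when the relative L2 change of the
sample-plane field between successive iterations falls below the tolerance
(default 10⁻⁴) or at the iteration cap (default 100).  Initialization is a
flat unit-amplitude field by default; back-propagated first-plane amplitude
and user-provided starts are available.  No support or positivity
constraints are applied, and there is no over-relaxation: the averaging
update is used exactly as stated.

Convergence behaviour worth knowing: intensity is blind to phase at low
spatial frequencies (the contrast transfer goes as sin(πλz f²) → 0 as
f → 0), so the lowest-frequency phase modes of a specimen converge with a
long ~1/t tail.  On 256×256 fields with the default tissue phantom the
10⁻⁴ stopping rule fires after roughly 150–260 iterations depending on the
realization, even though the reconstruction error is already small after
~50–100 iterations (amplitude RMSE < 0.01); smaller fields converge faster
(e.g. ~75 iterations at 128×128).  Both sweep patterns (sample-plane round
trips, the implemented default, and sequential plane-to-plane transfer)
show the same tail; the iteration count is physics-, not
implementation-limited.  With two heights only, residual twin-image
artifacts remain and grow as the two planes move closer together
(the per-frequency two-height system has determinant ∝ sin(πλΔz f²)); this
ill-conditioned regime is exactly where the learned reconstructor earns its
keep.

## The FIN network

FIN maps M normalized intensity holograms directly to the real and
imaginary parts of the sample field.  The architecture is residual-in-
residual:

* a 1×1 convolution (head) lifts the M planes to c channels;
* G SPAF groups follow.  Each group owns ONE SPAF module applied twice
  (recursion with full parameter sharing); every application adds its own
  input, and the group adds its input to its output;
* a long skip adds the head output to the last group's output;
* a 1×1 convolution (tail) projects to the 2 output channels.

A SPAF module: per-channel 2D DFT → centered (2k+1)² window around DC →
real-weighted linear map → zero-filled embedding → inverse DFT → real part
→ PReLU (learnable scalar slope per module, init 0.25).  Two weight
layouts: *full* (Eq.-1-style dense mixing, W ∈ ℝ^{c×c×(2k+1)×(2k+1)}) and
*shrunk* (channel-shared, W′ ∈ ℝ^{c×(2k+1)×(2k+1)}), the latter c× smaller;
full reduces exactly to shrunk when its weights are shared across the
input-channel axis.  Window half-sizes decrease across groups (a pyramid),
so early groups see wide frequency support and later groups refine low
frequencies.  For even grid sizes the centered window places DC at index
⌊N/2⌋ of the shifted view.

Two properties of the real-weight spectral map shape the design:

* For a real input, taking the real part after the inverse DFT means only
  the (u,v) → (−u,−v) *even* part of the weights acts: each SPAF layer is,
  linearly, a bank of real zero-phase filters.  The quadrature components a
  holographic inverse needs emerge only through PReLU and depth.
* In shrunk mode the channels are summed before weighting, so — linearly —
  every group filters the *same* single combination of the input planes.
  A two-height inversion needs independent filters per input plane, which
  the dense (full) layout provides.  The package therefore supports
  per-group modes; the recommended small-model layout is full in the first
  group (the physics inversion) and shrunk in the later groups (regularized
  refinement), which also keeps the parameter count modest.

Input normalization is scale-equivariant: the stack is divided by one
common scale s² (its mean intensity over all planes) and the output field
is multiplied by s.  Energy conservation ties the mean hologram intensity
to the mean squared object amplitude, so this makes the network exactly
equivariant to global illumination/transmission scaling — per-plane mean
normalization (the more obvious choice) destroys both the inter-plane
exposure ratios and the absolute level, and measurably biases the
reconstructed amplitude of specimen classes brighter or darker than the
training class.

The input field-of-view is fixed at build time (the frequency-window
weights are grid-specific); larger holograms must be tiled.  The network
and its training loop are implemented in numpy with analytic
backpropagation — the spectral layers' gradients are the adjoint DFT
operations (the adjoint of an unnormalized forward DFT is N²·inverse DFT) —
and are verified against central finite differences in the test suite.

Weight initialization: SPAF weights uniform in ±1/(c·(2k+1)); head/tail
1×1 convolutions Gaussian with 1/√fan_in scale and zero biases; SPAF
modules carry no biases.

## Training

Loss: L = α·L_MAE + β·L_complex + γ·L_percep with α, β, γ = 0.5, 1, 0.5.
L_MAE sums absolute differences over both output channels divided by the
pixel count n = H·W; L_complex is the mean absolute difference of the 2D
DFTs of the complex fields assembled from the (real, imaginary) channel
pairs, divided by the same n; L_percep is the mean squared distance between
low-level features of the amplitude images.  The feature extractor is
pluggable; the default is a fixed-seed two-layer random convolutional stack
(4 then 8 filters of 3×3, ReLU between) — deterministic, training-free, and
sufficient as a structural-similarity prior at this scale.  A pretrained
CNN wrapper can be substituted through the same two-method interface
(`features`, `backward`).

Optimization is Adam (β = 0.9/0.999, default lr 10⁻³) under cosine
annealing with warm restarts (first period 50 epochs, period doubling,
floor lr/100).  Augmentation applies one random rotation from
{0°, 90°, 180°, 270°} per sample per epoch to inputs and targets alike.
The train/validation split is 6:1 by phantom, and the returned model is the
checkpoint with the lowest validation loss.  Runs are bit-reproducible
given the config seed.  `transfer_finetune` is the same loop started from
trained weights; zero epochs returns the model untouched.

Desk-scale regime used by the tests and examples: 64×64 fields, ≤128
(stack, target) pairs, a few hundred epochs in minutes on one CPU.  Two
practical findings are baked into the recommended recipes: optimization of
the spectral weights benefits from a high-lr phase (~10⁻²) followed by
explicit low-lr stages rather than one long anneal, and presenting each
phantom under several independent sensor-noise realizations teaches the
network to denoise flat regions, which is what its external (unseen
specimen class) structural similarity is most sensitive to.

## Evaluation

SSIM uses the standard Gaussian-window form (11×11, σ = 1.5, K₁ = 0.01,
K₂ = 0.03), with the dynamic range taken from the reference image;
phase images are mapped from [−π, π] to [0, 1] first.  Amplitude and phase
RMSE are computed after removing the single global phase offset that
minimizes the L2 phase difference — holographic reconstructions carry an
arbitrary global phase, which is a gauge, not an error; phase RMSE uses the
wrapped difference and is bounded by π.  Reports aggregate per-FOV rows as
mean ± SD.  SSIM on mostly-flat fields is dominated by whatever noise or
hallucinated texture sits in the flat regions (local variances are tiny, so
the structure term is unforgiving there); that is worth remembering when
comparing specimen classes of different sparsity.

## Reproducibility plumbing

Hologram stacks are multi-page float32 TIFFs with YAML sidecars
(distances_um, pitch_um, wavelength_um, seed); complex fields are npz
archives (real, imag, pitch_um, wavelength_um); checkpoints embed the
architecture config as JSON next to the parameter arrays; traces are CSV;
reports YAML.  Arrays are row-major with the origin top-left and 0-based
indices.  `run_pipeline` writes a manifest of content checksums: identical
configs reproduce identical files.  A thin `finholo` CLI (simulate,
superres, autofocus, mhpr, train, infer, evaluate, pipeline) wraps the
library; exit codes are 0 (success), 2 (invalid configuration), 3
(degenerate input).

## Known limitations

* The iteration counts at which the 10⁻⁴ MH-PR stopping rule fires on
  256×256 fields exceed 100 for strongly phase-textured specimens (see the
  convergence discussion above); the practical reconstruction quality
  plateaus much earlier.
* Desk-scale FIN beats the classical solver where that solver is genuinely
  limited (close two-height spacing, noisy data); on well-conditioned,
  noise-free synthetic stacks a fully converged MH-PR is near-exact and the
  small learned model does not outperform it.
* Autofocusing assumes edge-bearing objects; very smooth textures give
  shallow score landscapes.
* Propagation assumes scalar, fully coherent, monochromatic illumination
  and thin objects; none of the vectorial, partially coherent, or thick-
  sample regimes are modeled.
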