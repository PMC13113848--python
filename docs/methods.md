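# Methods

## Problem setting

A flexible ultrasound array conforms to the body surface, so its element
positions — and with them every time of flight (ToF) used by delay-and-sum
(DAS) beamforming — change from session to session. `flexbeam` implements a
study pipeline around this problem: it synthesizes flat-array RF channel
data, manufactures paired (curved pre-delay RF, ground-truth delayed RF)
datasets by *artificial curvature*, reconstructs reference images with DAS,
and trains DNPAD — an adversarial network that predicts delayed RF directly
from raw RF, bypassing explicit shape estimation and delay computation — plus
a frequency-domain evaluation suite for RF-level signal variation.

## Array geometry

The array is a 1-D row of point elements (width and kerf are metadata only;
no aperture integration — the ToF model is point-to-point). Flat layouts put
element `i` at `x_i = (i - (N-1)/2) * pitch`, `z = 0`. A bent array lies on a
circular arc of radius `R` with its apex at the origin, tangent to `z = 0`,
bowing toward the medium (`z > 0`); spacing is the pitch measured *along the
arc*, since physical bending preserves surface distance:

    x_i = R sin(s_i / R),   z_i = R (1 - cos(s_i / R)),   s_i = (i - (N-1)/2) p.

The literature uses both "convex" and "concave" for this bending sense; only
the one sense (elements toward the medium) is modelled — the ToF difference
is antisymmetric in the bending sign and nothing downstream depends on it.

Defaults follow the prototype: 128 elements, 1 mm pitch (0.8 mm width +
0.2 mm kerf), 5 MHz center frequency, 62.5 MHz sampling, 3712 axial samples.
A reduced *desk array* (16 elements, 464 samples, same pitch/frequency/
sampling) is first-class for tests and desk-scale studies.

## RF simulator

Acquisitions use a walking single-element transmit: event `s` fires element
`s` and all 128 channels receive, giving the (axial, channel, scanline)
tensor. Echoes are Gaussian-modulated sinusoids (`scipy.signal.gausspulse`,
5 MHz, fractional bandwidth 0.6 at −6 dB — the bandwidth is a package choice;
only the center frequency is prescribed) at the two-way ToF of each point
scatterer, in a homogeneous medium with c = 1.540 mm/µs (the standard
tissue-mimicking-phantom value; configurable). No attenuation, directivity,
or multiple scattering: the simulator exists to exercise delay logic with
closed-form oracle math, and passing tests say nothing about tissue realism,
speckle, or aberration in real data.

The emulated study design: experiments enumerate (voltage × repositioning),
voltage acting as a pure amplitude gain numerically equal to the voltage
(only ratios matter), repositioning as one rigid phantom offset drawn per
experiment (default std 0.5 mm); within an experiment, consecutive
acquisitions differ only by white Gaussian system noise of std
`noise_sigma × gain` (desk default `noise_sigma = 0.002`, a visible but
signal-preserving floor). All randomness flows from explicit seeds.

## Artificial curvature

For each channel/scanline trace the flat-geometry ToF `T_f(z)` and the
curved ToF `T_c(z)` are computed on a dense depth grid (one node per RF
sample — a coarse grid leaves kinks where the delay varies fast). The
synthetic curved trace is the time remap

    curved(t) = flat(t + δ(t)),   δ(T_c(z)) = T_f(z) − T_c(z),

with δ interpolated onto the uniform sample grid, edge-extrapolated beyond
the focal-time range (this makes `R → ∞` an exact identity), and reads
outside the recorded window zero-filled. Sampling `curved` at `T_c`
reproduces the ground-truth delayed data `flat(T_f)` — the pair used for
training. Two degeneracies are intrinsic and documented rather than hidden:

* **Fold**: for depths above the bent element plane, `T_c` *decreases* with
  depth, so those times map to two depths and no single-valued remap exists.
  The warp uses the monotone branch (from the ToF minimum on); consistency
  checks therefore use focal grids that start below the element plane
  (≥ 1 mm on the desk array), which is also the physically imageable region.
* **Window truncation**: where `T_c` exceeds the recorded window the curved
  array simply never recorded the data; round-trip comparisons restrict to
  in-window reads.

Fractional delays use Catmull-Rom cubic interpolation (exact at the sample
points, so integer-sample delays reduce to index shifts). Linear
interpolation was rejected: at 12.5 samples per carrier cycle its double
application alone costs 3–4 % RMS, larger than the 1 % round-trip
consistency budget; cubic brings the in-window error to ~0.5 %.

The curvature sweep expands one acquisition into one paired sample per
radius, 300–800 mm in 5 mm steps → 101 pairs (desk runs use coarser steps).
A warning (not an error) flags radii outside the mechanically feasible
300–800 mm band.

## Delay-and-sum reference

`compute_tof → delay_rf → sum_channels → envelope_log`: plain summation over
all channels (no apodization or aperture growth), envelope via the analytic
signal per scanline, normalization to the global maximum, 20 log10, clipped
at a 60 dB dynamic range. Scanline beams ride at the *flat* element lateral
positions for every curvature so paired data share one grid. The default
focal grid maps `n_focal` uniform round-trip times spanning the recorded
window to depths `z = c t / 2` (1024 points at full scale, 128 on the desk
array).

## Dataset plumbing

Axial resize 3712 → 1024 uses polyphase anti-aliased resampling
(`resample_poly`, ratio 8/29, linear-extension padding); sampling metadata is
rescaled. Normalization maps each tensor affinely onto [0, 1] with the
(min, max) recorded per pair so the map can be inverted — inversion matters:
summing a [0, 1]-offset cube is DC-dominated and degenerates the B-mode, so
every reconstruction from normalized data maps back to physical amplitudes
first. The split rule holds out whole acquisitions: per experiment, one
acquisition (all its curvatures) to test and one to validation, seeded and
logged; 4 × 24 acquisitions × 101 curvatures yields the 404/404 held-out
counts. (The originating study's printed train count of 8080 is inconsistent
with its own arithmetic — 4 × 24 × 101 − 808 = 8888; the rule, not the
count, is normative here.)

## DNPAD

A conditional image-to-image adversarial pair, implemented on a compact
in-repo numpy conv-net framework (`flexbeam.nn`: conv/transposed-conv/batch
norm/pooling layers with manual backpropagation, Adam, cosine annealing;
every backward pass is verified against finite differences in the tests).

* **Generator** — 3-level U-Net over one scanline section (channels × axial,
  128 × 1024 at full scale): 3×3 same-padded convs + batch norm + ReLU, 2×2
  max pooling, channel widths 1 → 64 → 128 → 256 with a 512-channel
  bottleneck at 16 × 128; decoder mirrors with 2×2 stride-2 transposed convs
  and concatenation skips; final 3×3 conv + sigmoid. Intermediate widths
  double per level (only the 1 → … → 512 endpoints are prescribed); one conv
  block per level keeps the full-scale probe cheap.
* **Discriminator** — five 4×4 conv layers (four stride-2 with batch norm +
  LeakyReLU(0.2), then a stride-1 same-padded conv to one channel + sigmoid
  patch map), operating on the concatenated (input, candidate) pair.
  Conditioning and hard 0/1 labels are conventional choices exposed in
  config (`conditional`, `label_smoothing`).
* **Losses/optimization** — generator: `BCE(D(x, G(x)), 1) + 10·L1(G(x), y)`;
  discriminator: BCE on real/fake. Adam (β₁ = 0.5, β₂ = 0.999), initial lr
  1e-4 with cosine annealing, batch size 4. Three variants differ *only* in
  input noise on the normalized pre-delay data: INO (none), GN0.001,
  GN0.01.

The public surface is `DNPADModel(split, …).fit() → DNPADResults` with the
training history, `summary()`, `predict()` and `reconstruct()`.

## Spectral evaluation

2-D FFT with the zero-frequency bin centered (`fftshift`; the standard
half-period rotation), log-magnitude maps `log(1 + |F|)`, and pairwise
difference maps computed complex-first (`|F₁ − F₂|`, then `log1p` for
display) — magnitudes are taken before logging since a complex log has no
real display. Sections default to the (axial × channel) slice at the center
scanline. Image MSE is the plain mean squared pixel difference. The
degeneracy these maps expose — RF-level differences that envelope detection
and log compression hide from B-mode inspection — is verified in the tests
with a constructed sub-resolution shift pair.

## Desk-scale study sizes

Tests and the acceptance script run the full pipeline at reduced size, as a
package design choice: 16-element/464-sample array, 128-point focal grid,
2–4 experiments × 3 acquisitions, 3–11 curvature radii, base channel width
4–8, 30 training epochs. The architecture probes still build the full-scale
128 × 1024 / 512-channel network. Full-scale training fidelity (the
originating study trained on a data-center GPU) is explicitly out of scope.

## Known limitations

* The noise-robustness finding reproduces only partially at desk scale: over
  5 seeded replicates the across-curvature reconstruction-MSE variance of
  GN0.001 is ≤ INO in the majority of runs, but GN0.01 destabilizes training
  in a minority of seeds and fails the majority test — σ = 0.01 is a large
  perturbation for ~20k-parameter models trained on 96 scanlines. The
  corresponding acceptance test is left failing by design and the analysis
  is recorded alongside it.
* Point-scatterer simulator: no speckle, attenuation, directivity, or
  refraction under bending.
* The warp cannot represent fold-region (above-element-plane) or
  out-of-window data; consistency guarantees apply to the imageable,
  recorded region.
* B-mode geometry is the rectilinear focal grid; no sector scan conversion.
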