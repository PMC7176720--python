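# Methods

## Forward model

A scene is a nonnegative fluorophore-density map on the camera grid.
Frame (a, p) of a raw stack is

    E[frame] = blur_OTF( S(r) · [1 + m cos(2π k_a·r + ψ_p)] ) · dose + b
    frame    = Poisson(E) + N(0, σ_read)

with the incoherent widefield OTF of a circular pupil (cutoff
`2·NA/λ` in cycles/px; defaults NA 1.45, λ 525 nm, 60 nm pixels give
0.331 cycles/px), modulation depth m, background b and read noise σ_read.
The dose scale maps the brightest widefield pixel to `photon_budget /
low_light_factor` expected photons. Frames are ordered angle-major
(a₁p₁…a₁p₅, a₂p₁, …) — this ordering is the contract for every consumer,
including the 3-frame selection (indices 0, 5, 10).

Defaults and rationale:

- `pattern_frequency_fraction = 0.85` of the OTF cutoff and `m = 0.8`:
  a typical commercial-SIM operating point; commercial instruments do not
  publish their pattern parameters, so these are explicit stand-ins.
- Angles span π (a sinusoid at Θ and Θ+π is the same pattern); phases span
  2π evenly, which makes the phase-mixing matrix a DFT matrix.
- `photon_budget = 200` photons/frame at the brightest pixel with
  `read_noise_sd = 1`: normal-light conditions where classical
  reconstruction is clean; dividing the dose by 100 (1 % laser / 20 ms vs
  10 % / 200 ms) leaves ~2 expected photons and reproduces the low-SNR
  regime in which classical reconstruction visibly fails.
- Pattern vectors are snapped to the nearest DFT bin of the simulation grid
  by default, making the illumination exactly periodic: order separation
  and order shifting are then leakage-free and the simulator is an exact
  oracle for the reconstruction. `snap_pattern_to_grid=False` emulates
  arbitrary instrument frequencies (see *Parameter estimation* below).
- Scenes are rendered at the camera grid (no supersampling): the data being
  emulated are camera-sampled, and the point of the simulator is a
  controlled, fast test bed, not optical rigor. Sub-pixel placement is
  supported where it matters (the two-point resolution phantom uses
  bilinear splatting).

Scene classes emulate the fixed-cell structures used for network training:
`filament` (smooth random-walk curves ~2 px wide, microtubule/F-actin-like),
`puncta` (isolated diffraction-scale spots, adhesion-like) and `blob`
(textured ellipsoids, mitochondria-like). What the generator does **not**
emulate: out-of-focus background, sample drift, spectral bleed-through,
EMCCD excess noise, spatially varying illumination gain. Passing tests
therefore demonstrate the correctness of the algorithms and the learnability
of the synthetic task family, not performance on real microscope data.

## Classical reconstruction

Per angle, the P phase-stepped spectra are unmixed into orders
q = −(P−1)/2 … +(P−1)/2 by the pseudo-inverse of `M[k,q] = exp(i q ψ_k)`.
Each order is zero-padded to the 2x grid, shifted to its true position by a
real-space phase ramp (exact for off-grid k_p), and merged with the
generalized Wiener filter; the result is apodized with a triangle filter to
`cutoff + |k_p|`, inverse-transformed and clipped at zero. Orders ±2 of a
5-phase acquisition are separated but excluded from the default merge: the
simulated illumination is a pure sinusoid, so they carry no signal
(`orders_to_use` overrides this for genuine three-beam data).

Numerical choices: `wiener_w = 0.05` (relative to the unit-normalized OTF)
balances sharpening against noise amplification at the synthetic photon
budgets; the output grid is fixed at 2x the input; negative clipping is
skipped when the caller needs the linear spectrum (support measurements).

## Parameter estimation

When pattern parameters are not taken from simulator metadata they are
estimated per angle: the order-0/order-1 product field
`g(r) = conj(u0)·u1` has a phase ramp at k_p; its spectral peak is located
to sub-bin precision by two zoomed DFT stages, a ±1-bin residual grid scan
(spectral leakage from sparse scenes can favor a sidelobe), and Nelder–Mead
refinement of the residual of the complex regression

    c1(f + k_p) = (m/2) e^{iψ0} OTF(f + k_p) S(f),

whose coefficient finally yields ψ0 and m. A peak-significance gate
(peak ≥ 8x the median masked correlation magnitude) turns pure-noise inputs
into an explicit estimation error rather than a garbage reconstruction.

Accuracy, noise-free: with grid-periodic patterns (the simulator default)
recovery is essentially exact (|Δk| ~1e-7 cycles/px, ψ ~1e-4 rad, every
seed tested). With off-grid patterns at 256 px, |Δk| stays below 2e-4 but
the ψ error grows as 2π·|Δk|·(content centroid distance) — typically below
0.02 rad, though sparse scenes can exceed it. This asymmetry is a known
limitation; reconstruction quality is insensitive to it because the known
vs estimated paths agree to Pearson r > 0.999 on the scenes tested.

## Networks and training

All variants share one U-Net: per level two 3x3 convolutions + ReLU, 2x2
max-pool down, 2x2 transposed-convolution up, skip concatenation, linear
1x1 output; features double per level. The stacked variant (scU-Net) feeds
U-Net #1's output (ReLU-gated) into U-Net #2 and concatenates U-Net #1's
decoder features into U-Net #2's encoder at matching scales; disabling the
cross skips is supported and measurably reduces the parameter count.

The engine is a small tape-based reverse-mode autodiff on numpy (float64
end to end), which makes training runs bit-reproducible given the seed —
there is no threading or GPU nondeterminism to document. Adam with lr 1e-3,
batch 4 are the package defaults at desk scale (1e-4 suits longer runs);
He-normal initialization seeded from the network config.

Loss: per-pixel `|U−V| + 5(U−V)²` (`l1_l2`). The signed variant
(`as_printed`, first term ΣU−V without absolute value) is implemented and
tested — it admits a degenerate minimizer at constant residual −0.1 and can
go negative — but is not the training default.

Problem sizes: the package trains on 32 px raw patches bicubic-upsampled to
the 64 px network grid (the same 2x geometry as the full-size 128→256
pipeline), with depth-3, width-8 U-Nets, chosen so that complete
train-and-evaluate studies run in minutes on a single CPU core. Statements
about full-scale behaviour (depth 4, width 64, 256 px patches, ~2000
epochs) are architectural, not measured here.

Normalization: one scalar maximum per domain (input, target), computed over
the **training portion only** and persisted in the checkpoint; validation,
test and inference reuse the training constants. (Computing the maximum
over the whole dataset would leak test intensities into training; the
stricter reading is deliberate and documented.) Dataset splits are random
at the *source-stack* level so neighbouring patches never straddle the
train/test boundary — stricter than patch-level splitting, again to prevent
leakage.

Inference tiles full frames with feathered (raised-cosine) blending; a
single tile covering the frame is an exact pass-through.

## Metrics

PSNR `20 log10(255/RMSE)` on the 8-bit scale (normalized images are mapped
to [0, 255] first — the convention implied by the 255 numerator); NRMSE
= RMSE / σ of the ground truth; SSIM as the global two-term form with
C₁ = (0.01 L)², C₂ = (0.03 L)². The σ symbols in SSIM's second term are
interpreted as standard deviations (σ² variances), the standard convention
consistent with those constants; the variance-as-σ reading is available as
a flag, and a 7x7 windowed mean-SSIM likewise.

Resolution is estimated by decorrelation analysis: the cross-correlation
d(r) between the spectrum and its phase-only counterpart under growing
low-pass masks (Nr = 50 radii), repeated over Ng = 10 Gaussian high-pass
pre-filters; the cutoff is the highest peak frequency across curves (the
global curve maximum, endpoint included — a noise-dominated curve rises
monotonically and correctly peaks at Nyquist), and resolution is
`2·pixel_size / cutoff`. Constant images return NaN with a warning.

RSE/RSP fit a resolution-scaling function restricted to an isotropic
Gaussian blur plus affine intensity map (closed-form α, β per σ; bounded
1-D search over σ including σ = 0), then report the residual RMSE and the
Pearson correlation at the optimum. The general (non-Gaussian) kernel
estimation of the original error-mapping method is not reproduced; for
synthetic data the Gaussian family is sufficient and keeps the fit convex
in practice.

## Known limitations

- The ψ-offset estimation bias for off-grid patterns described above.
- The background-rejection default (≥1 % of pixels above median + 3 MAD)
  keeps patches of pure Gaussian background (whose 3-MAD tail is ~2 %);
  it reliably rejects empty/zero patches, and the rule is configurable and
  recorded. Matching a human's manual culling was not the goal.
- Low-light evaluation compares images after per-patch peak normalization;
  absolute-intensity fidelity is not scored.
- 3D (z-stack) SIM, polarization, drift and gain registers are out of scope.
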