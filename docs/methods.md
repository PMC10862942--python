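# Methods

## Physical model

A single-mask phase contrast imaging system places a periodic absorption
mask (period twice the detector pixel pitch) just upstream of the
object, aligned so that the center of each transparent slit falls on
every other pixel boundary. `smpci` models the recorded pixel intensity
with the linearized transport-of-intensity equation (TIE)

    I(z) = I(0) − (z/k) [∇⊥I(0)·∇⊥φ + I(0) ∇⊥²φ],

with `I(0) = T(x,y)·M(x)` the transmitted intensity at the object plane,
`T` the object transmission, `M` the mask transmission, `φ` the phase
shift, `z` the object-to-detector distance and `k = 2π/λ` the
wavenumber. Because the mask is high contrast, the gradient cross term
is dominated by `T·∂ₓM` and cannot be dropped (unlike in plain
propagation-based imaging, where `I = I₀(1 − (z/k)∇⊥²φ)` suffices).

Writing the mask as a cosine series `M(x) = Σ Cₘ cos(πmx/p)` with
period `2p` and integrating the TIE over one pixel under the assumption
that `T`, `∂ₓφ` and `∇⊥²φ` vary slowly across a pixel gives the
two-coefficient closed form implemented in
`forward_tie.single_mask_image_closed_form`:

    Iₙ = wₑ Tₙ (1 − Lₙ) + α (−1)ⁿ Tₙ Dₙ

with per-pixel fields `Tₙ` (transmission), `Lₙ = (z/k)⟨∇⊥²φ⟩`
(Laplacian-phase, the propagation-based edge signal) and
`Dₙ = (z/k)⟨∂ₓφ⟩` (the beamlet displacement at the detector, in meters,
equal to `z` times the refraction angle), and exactly two mask numbers:

* **effective aperture** `wₑ = C₀·p` — the mask transmission integrated
  over any one pixel (the integral is pixel-independent because the
  period is exactly `2p`);
* **mask contrast** `α = 2·ΣC₂ₘ₊₁` — the transmission difference
  between slit-center and strip-center pixel boundaries; equivalently
  `M((n+1)p) − M(np) = −α(−1)ⁿ`.

The alternating `(−1)ⁿ` factor is the origin of the bright/dark fringe
pattern between adjacent columns: refraction displaces each
mask-defined beamlet sideways by `Dₙ`, enriching one column of each
pair at the expense of the other.

Sign and index conventions (the source derivation leaves both free):
phase retardation is negative, `φ = −k·δ·t` for projected thickness
`t`; slit centers sit at even pixel boundaries `x = 2jp`; the fringe
sign is `s_n = (−1)^(n+parity)` with default `parity = 0`, chosen so a
positive `Dₙ` brightens even columns. Flipping either convention flips
only the sign of the retrieved DPC channel; the `parity` flag absorbs
the choice.

`single_mask_image_integrated` evaluates the three transport integrals
(`∫T·M`, `∫T·∂ₓM·∂ₓφ`, `∫T·M·∇⊥²φ`) per pixel directly on the fine
grid, without the slow-variation step, and is used throughout the tests
as the oracle for the closed form. Cell-centered Riemann sums
commensurate with the pixel grid integrate every cosine harmonic
exactly (the sampled phases telescope over each pixel), so the flat
field reproduces `wₑ` to rounding precision rather than to O(Δx²).

## Retrieval

One sample+mask exposure and one flat (mask-only, `Iₙ = wₑ`) exposure
are acquired. Flat correction gives
`Īₙ = Tₙ(1−Lₙ) + s_n (α/wₑ) Tₙ Dₙ`, and neighbor pairs separate the
channels:

    Tₙ(1−Lₙ) ≈ (Īₙ + Īₙ₊₁)/2,
    Dₙ ≈ s_n (wₑ/α) (Īₙ − Īₙ₊₁)/(Īₙ + Īₙ₊₁),

where the second formula uses the weak-Laplacian approximation
`1 − Lₙ ≈ 1`. These per-pair relations are exact when `Tₙ, Dₙ` are
constant within a pair and `Lₙ = 0` (verified to machine precision in
the tests).

**Attenuation-gradient crosstalk.** For real objects the smooth
transmission gradient also contributes to the pair difference and leaks
into the DPC estimate at first order in the pixel size:
`ΔDₙ ≈ (wₑ/2α)·p·∂ₓ ln T`. At this package's default layout
(wₑ = 27.5 µm, p = 55 µm, z = 0.6 m) the ratio of crosstalk to signal
for a single material is `wₑ·µ·p/(2zδ)` — about 13% for PMMA at
20 keV, independent of position. The retrieval therefore offers three
estimators:

* `pairing="disjoint"` — the plain per-pair formulas on pairs
  (2j, 2j+1); half-width output at pair centers; carries the full
  first-order crosstalk. This is the baseline single-shot method.
* `pairing="sliding"` — every adjacent pair, then the two pair
  estimates covering each pixel are averaged. Because the crosstalk
  alternates sign between consecutive pairs it cancels to first order,
  leaving an O(p²) residual. Output is full width with a triangular
  [1, 2, 1]/4 column kernel (neighboring columns are correlated).
* `sliding` with `pb_gradient_correction=True` — the smooth per-pair
  gradient predicted from the retrieved PB channel is subtracted from
  each pair difference before the ratio, suppressing the residual
  further; the effective column kernel becomes [1, 0, 1]/2.

Accuracy statements in the tests compare against ground truth averaged
with the estimator's documented output kernel (resolution-matched
comparison), the appropriate metric for estimators with a finite
support kernel. Retrieval errors are quoted relative to the profile's
peak |Dₙ| in the evaluated region, since `Dₙ` passes through zero.
Uniform-attenuation, zero-phase inputs give identically zero DPC; for
smoothly varying attenuation with zero phase the residual is the
crosstalk described above, which the balanced estimators suppress by
more than an order of magnitude.

The division in the flat correction is guarded (flat pixels at or below
`1e−6 ×` the median are flagged invalid and propagate as missing
values), as is the pair-sum denominator.

## Wave-optics cross-check

An independent angular-spectrum simulation validates the transport
model: the exit field `U = sqrt(T·M)·exp(iφ)` (mask treated as a pure
absorber) is propagated with the exact scalar transfer function
`exp(ikz·sqrt(1 − (λf)²))` (evanescent components zeroed), the
intensity is blurred with a Gaussian of the projected source width
(7 µm focal spot default) and binned onto detector pixels. Propagation
is 1D-in-x per detector row — the mask modulates in x only, and this
keeps the full comparison under a second on one core; a 2D mode exists
behind a flag. Periodic FFT boundaries are handled by extending the
domain with an eight-mask-period guard band in which the object
deviation is tapered to vacuum with a raised cosine; the mask continues
periodically into the guard.

At the default layout the flat-corrected transport-model and wave
profiles agree to ~0.04% RMS for both reference masks (an ideal 50%
duty square wave and the sinusoid `M = 0.5 + 0.5·cos(πx/p)`), with
identical fringe parity — far inside the 5% acceptance band. Agreement
degrades as the object feature scale approaches the pixel scale, which
is the slow-variation limit of the closed form, not a defect of either
implementation.

Sampling notes: the angular-spectrum guard warns when
`z > N·Δx²/λ` (transfer-function chirp aliasing); wave simulations use
≥64 samples per mask half-pixel period (oversampling `s = 64`).
Truncated square-wave masks ring below zero by up to ~9% of the step
(Gibbs); the exit-field builder clips values in [−0.1, 0) to zero and
rejects anything more negative.

## Synthetic data

Phantoms are analytic projections sampled on a fine grid that
oversamples the pixel grid by an integer factor (default `s = 16`;
`s = 32` where derivative accuracy near cylinder edges matters,
`s = 64` for wave runs):

* **cylinder** — chord thickness `t = 2·sqrt(R² − x²)`; defaults mirror
  the experimental sample, a 3 mm diameter PMMA rod;
* **tube** — nested cylinders (wall / liquid fill / coaxial rod) with
  per-material chord lengths, mimicking the multi-material sample;
* **gaussian blob** — band-limited `φ = −A_φ·G`, `T = 1 − A_att·G`,
  used for oracle-agreement and convergence studies. Defaults
  `A_φ = 1 rad`, `A_att = 1e−3` reproduce the phase-dominant response
  of PMMA-like soft matter at 20 keV (µ/(kδ) ≈ 1e−3 per radian);
  stronger-phase variants (tens of radians, matching a few mm of
  plastic) are used where visible fringes are wanted.

Material constants ship as a small built-in table (PMMA, water,
polycarbonate at the 20 keV design energy), with `δ` from
`r_e λ² n_e / 2π` and `µ` from standard mass-attenuation compilations;
both are config-overridable. The 20 keV monochromatic design energy
stands in for the 40 kVp polychromatic tube spectrum of the physical
system, whose effective energy is not better constrained; all
energy-dependent quantities flow through the config. The model is
parallel-beam by default; the cone-beam geometry (SOD = ODD = 60 cm,
M ≈ 2) is available only as an effective-distance/projected-source
scaling via the `magnification` field, off by default.

What the synthetic data does **not** emulate: polychromaticity and
beam hardening, detector PSF and charge sharing, scatter/dark-field,
mask fabrication defects, and the ~52 µm (vs 110 µm = 2p) experimental
mask period that projection magnification reconciles. Passing tests
demonstrate internal consistency of the model chain and its agreement
with scalar wave optics under these idealizations, not end-to-end
fidelity to a physical bench.

## Numerical choices

* Derivatives: central differences (one-sided at boundaries) for
  gradients; 3-point second differences per axis for the Laplacian;
  both second-order, verified by ~4× error reduction under grid
  halving.
* Mask pixel integrals: composite 12-point Gauss–Legendre with panel
  count scaling with the highest harmonic (~1e−14 accuracy), kept as a
  numeric check against the closed forms `C₀p` and `−2ΣC₂ₘ₊₁(−1)ⁿ`.
* Closed-form/pixel relations require an aligned mask and raise
  `MaskAlignmentError` for `offset ≠ 0`; misaligned masks remain
  representable for the wave oracle.
* Negative model intensities (strong refraction, `|αTD| > wₑT(1−L)`)
  trigger a validity warning and are never silently clipped.
* Poisson noise is applied by scaling the flat level to a target count
  number, drawing, and scaling back; all randomness flows through
  seeded `numpy` generators recorded in metadata.
* Problem sizes in tests and the acceptance script (detector widths of
  64–128 pixels, a handful of rows, oversampling 16–64) are chosen so
  every property is resolved with comfortable margin while the whole
  chain stays interactive on one core.

## Known limitations

* The closed form drops the `M·∂ₓT` coupling; with attenuation
  amplitude `a` and feature scale `ℓ` this leaves a first-order
  alternating residual ≈ `a·(p/ℓ)·p/π²` relative to `wₑ` between the
  closed and integrated forms (quantified in the tests). The quoted
  second-order convergence between the two forms applies to the
  pure-phase regime.
* The disjoint estimator's 13%-scale attenuation-gradient crosstalk on
  strongly attenuating objects is inherent to the plain per-pair
  formulas; use the sliding estimator when quantitative `Dₙ` matters.
* Phase unwrapping/integration (recovering `φ` from `Dₙ`), dark-field
  retrieval and spectral methods are out of scope.
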