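# Methods

This note documents the models, numerical choices and limitations behind
`qusatten`, in the spirit of a methods appendix: what is simulated, what the
estimators assume, which knobs matter, and what the tests do and do not
demonstrate.

## Physical model and units

All spatial quantities are in cm, time in µs, frequency in MHz, attenuation
in nepers (1 Np = 8.686 dB; converters in `qusatten.units`). The medium is a
host matrix with sub-wavelength scatterers; attenuation is strictly
frequency-linear, α(f) = α₀·f with α₀ in Np/(cm·MHz); dispersion and
multiple scattering are not modeled. A single zero-angle plane wave is
transmitted by a 128-element, 298 µm pitch, 5.2 MHz linear array sampled at
20.8 MHz (all configurable via `ProbeGeometry`). Under dense in-phase
backscatter, ensemble backscattered intensity obeys
I_r(z, f) = A²·exp(−4 α(f) z); consistent with that regime, geometric
spreading on receive is not applied in either simulator. The transmit pulse
is a Gaussian-enveloped sinusoid; its fractional bandwidth (default 60%,
FWHM of the amplitude spectrum) is the one free pulse parameter.

## RF simulators

**Pointwise oracle.** Sums one echo per (element, scatterer) pair, delayed
by the two-way time (plane-wave leg z plus spherical receive leg r). The
attenuation filter exp(−ᾱ f (z+r)) is applied in closed form: a Gaussian
amplitude spectrum times a decaying exponential in f is again Gaussian,
with carrier downshifted by β σ_f² (β the path integral of α₀ in Np/MHz)
and amplitude exp(−β f_c + β²σ_f²/2). The attenuation path average ᾱ is
taken along the scatterer's vertical column — exact for laterally uniform
and layered media, approximate near steep lateral interfaces. Cost is
O(elements × scatterers); it is the ground-truth generator for small scenes.

**Fast convolutional model.** Scatterer amplitudes are binned onto a
pitch-spaced column × depth grid (z = c·t/2) covering the whole phantom,
low-pass filtered per depth block with the zero-phase kernel
P(f)·exp(−2 f ∫₀^z α₀ dz′) (Hann-windowed 50% overlap-add, 128-sample
blocks), and propagated to the array by the inverse Stolt map of the
zero-angle plane-wave geometry. This restores the hyperbolic lateral
coherence real echoes have — migrating laterally *incoherent* per-element
noise redistributes deep energy obliquely and visibly steepens the measured
decay, so coherence is not optional. Three numerical safeguards matter:

- **Lateral band limit.** The reflectivity spectrum is raised-cosine capped
  at a frequency-independent k_x (default 0.25·f_lo/c ≈ 3.4 cycles/cm). An
  angle-based taper would cut progressively more of the spectrum as the
  band downshifts with depth and masquerade as extra attenuation; a fixed
  k_x cap is depth-neutral. The cap also keeps synthesized beams paraxial
  so that finite-aperture loss over the imaging depth is negligible, which
  is the regime the intensity model assumes.
- **Spectral resampling.** Both the inverse map and the migration resample
  spectra whose phase encodes depth; naive linear interpolation attenuates
  off-origin content progressively with depth (an artificial decay of order
  several percent). Spectra are therefore demodulated by the record-center
  phase before cubic interpolation, the exact phase being restored at the
  resampled frequencies, with 8× zero-padding.
- **Scene wider than the aperture.** Default phantoms extend 0.9 cm beyond
  the array on each side. Tissue does not end at the probe edge; without
  the margin the recorded region loses energy laterally with depth and the
  reference-free estimator (unlike the reference-normalized ones) inherits
  the artifact.

Residual imperfection: image lines within a few mm of the aperture edge are
reconstructed from one-sided data and read a few percent high; ROI masks in
the study helpers exclude them. Scatterer density defaults to 12 per
resolution cell (fully developed, Rayleigh-enveloped speckle); electronic
noise is off by default and available as additive white Gaussian at a
configurable SNR.

## Beamforming

Stolt f–k migration for a zero-angle plane wave: data spectrum D(k_x, f)
maps to the image spectrum at k_z = f/c + √((f/c)² − k_x²), equivalently
f = c(k_z² + k_x²)/(2 k_z), with Jacobian (c/2)(1 − k_x²/k_z²); evanescent
components are zeroed. The output grid is one line per element and
z = c·t/2. A delay-and-sum beamformer with an
f-number-1 receive aperture serves as an independent cross-check: focal
spots agree within half a wavelength on point scenes.

The migration keeps the full aperture by default; an optional cosine edge
taper (``edge_taper_elements``) is available but off, since a per-column
gain never affects slope estimates and the taper was found to shift, not
remove, the edge artifacts.

## Attenuation estimators

**PWI.** `estimate_ac_pwi` is the plain contract: OLS of ln I_r on z over
the depth range (default 2–5.7 cm; the 2 cm floor excludes the near field,
6.5 cm is the maximum supported), slope divided by −4 and by `f_eff`
(default 5.2 MHz). On noiseless exponential profiles it is exact to machine
precision. `map_local_ac` builds the local map: square windows of
`pixel_size_lambda` wavelengths (8.5/17/25 presets; 17λ ≈ 5 mm ≈ 15–17
elements), 95% overlap in both directions, lateral intensity averaging
before the log (reduces speckle log-bias), OLS slope per window. Because a
broadband pulse's spectrum downshifts with depth (the log-intensity slope
tracks −4α₀·f̄(z), not −4α₀·f_c), each window's slope is by default divided
by the spectral centroid measured in that window (Hann periodograms,
laterally averaged; axial wavenumber maps to temporal frequency via
f = ν·c/2). The centroid band must cover essentially the whole downshifted
pulse support — default (0.2·f_c, 1.85·f_c) — since clipping the low tail
inflates the centroid and biases α₀ low by 1–2%. Passing `f_eff` instead
disables the correction. Windows with fit R² below a configurable threshold
are set to NaN (flagged, excluded from ROI averages), not dropped silently;
a machine-epsilon floor under the log survives exact zeros.

**SDM / SLDM.** Depth-resolved Welch-style spectra (5 mm Hann windows,
2.5 mm hop, laterally averaged periodograms) for sample and reference on a
common grid; SDM takes the per-frequency OLS depth-slope of the log
spectral ratio over all windows (not adjacent differences), SLDM the
two-point version at a proximal and distal window (defaults 2.5 and
5.0 cm). Both return α(f) curves; `ac_slope` converts a curve to α₀ by
zero-intercept least squares. The reference medium must have matched sound
speed (within 1%, enforced). All three estimators are invariant to an
overall RF gain.

## Study experiments (problem sizes)

`qusatten.study` packages the experiments the tests and the acceptance
script run:

- **Two-zone recovery**: 30 seeds of the two-zone phantom (0.079 | 0.107
  Np/(cm·MHz), lateral split), 17λ maps for zone means, all three pixel
  sizes for the variability curve; zone ROIs exclude 0.8 cm around the
  interface (local estimates near an interface mix both zones over the
  lateral spread of deep energy) and 0.5 cm at the aperture edges.
- **Method concordance**: 20 matched seeds of a uniform α₀ = 0.08 medium.
  All three methods analyze the same footprint (the plane minus 0.5 cm at
  the aperture ends), so the acquisition's speckle-driven decay
  fluctuation moves the three estimates together and the comparison
  isolates method differences. The per-acquisition PWI value is the
  global estimate — log-slope of the footprint-averaged intensity,
  normalized by the measured spectral centroid at mid-range — which is
  both lower-variance and more strongly correlated with the spectral
  methods than a mean over small-window map pixels. SDM/SLDM use 10 mm
  Welch windows against a reference medium at α₀ = 0.05 that is
  re-acquired (4 fresh realizations, spectra averaged) with every sample
  measurement, so reference uncertainty appears in the
  between-acquisition spread rather than as a shared offset.
- **PDFF**: noiseless round trip over the 0–100% grid, and 500 voxels at
  PDFF 3.7%, SNR 50 (complex noise std = total proton density / SNR).
- **Calibration**: 10⁴ null t-tests at n = 15 per arm; 10³ null
  correlations at n = 12.
- **Synthetic cohort**: per-organ volunteer draws (kidney/liver n = 12,
  pancreas n = 8, breast n = 3) with attenuation normal around the printed
  organ means/stds (two acquisitions averaged per volunteer) and PDFF
  log-normal matched to the printed center and IQR
  (σ = asinh(IQR/2m)/0.6745); log(PDFF)–α₀ correlation is checked for
  self-consistency against the generating process (a large draw with the
  same 12/12/8/3 organ proportions — the organ mix sets how much the
  high-fat anchor weighs in the pooled R²), not against the in-vivo
  headline value, which is not reproducible without the raw volunteer
  data.

## PDFF estimation

Signal model: s(TE) = (ρ_w + ρ_f·Σₚ aₚ e^{i2πf_p TE})·e^{i2πψTE}·e^{−TE·R2*}
with an 8-peak triglyceride spectrum (shifts 5.29…0.90 ppm against water at
4.70 ppm; amplitudes normalized to 1; values stored as overridable data), a
single effective R2\* shared by water and fat, and complex fitting by
variable projection: the complex amplitudes solve a linear least-squares
problem for each (ψ, R2\*), which a bounded trust-region search refines from
a small ψ multi-start (0, ±220 Hz — near half the main fat–water shift,
where swapped minima live); the lowest-residual solution wins. PDFF uses
amplitude magnitudes, so it is bounded in [0, 100]. Exact-zero PDFF voxels
are flagged and excluded from ROI summaries (mean, std, n, IQR), as are
non-converged fits. Bipolar-readout phase errors and T1 bias are not
modeled; magnitude-only fitting is not implemented.

## Statistics

Cohen's d uses the unweighted RMS of the two group stds (the form that
reproduces the printed phantom-table values; not the n-weighted pooled SD),
with |d| ≤ 0.2 / < 0.8 / ≥ 0.8 labeled small/medium/large. Bonferroni tiers
divide (0.05, 0.01, 0.001) by the number of tests, which the caller states
explicitly. The correlation p-value is the standard t-test on Pearson's r
with n − 2 degrees of freedom. Printed-table regeneration compares at ±1
unit in the last printed digit; the comparison-table effect sizes and two
organ PDFF relative errors do not reproduce from rounded inputs (they were
evidently computed from unrounded data) and are reported with a
`reproducible=False` flag rather than forced.

## What passing tests do and do not show

The synthetic data realize exactly the model the estimators invert —
frequency-linear attenuation, fully developed speckle, known sound speed,
no aberration, no electronic noise unless requested. Passing recovery tests
therefore validates the implementation and the estimator mathematics, not
clinical performance: real tissue adds sound-speed error (bias proportional
to it), aberration, non-Rayleigh scattering, interfaces, and system effects
that only the reference-phantom methods partially cancel. The in-vivo
correlation experiment is represented only through its arithmetic and a
self-consistent synthetic cohort.

## Known limitations

- Edge image lines (within ~0.3 cm of the aperture ends) read a few percent
  high; exclude them from ROIs, as the study helpers do.
- The pointwise oracle attenuates along the vertical column average, so it
  is approximate for media with strong lateral α₀ gradients.
- Only zero-angle plane-wave transmit is supported (no compounding).
- The fast simulator's lateral speckle correlation (~1/k_x cap ≈ 3 mm) is
  coarser than a diffraction-limited system would give; per-window lateral
  averaging therefore has fewer independent looks than the element count
  suggests, inflating map variance somewhat.
- SLDM inherits two-window variance; its defaults (2.5/5.0 cm) suit the
  default depth range only.
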