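# Methods

## Data model and conventions

An FS-FLIM cube is a 4-D non-negative integer tensor indexed
`(row, col, spectral_channel, time_bin)`, row-major, 0-based. Spectral
channels and time bins are **half-open intervals**: channel *k* covers
`[λ_min + kΔλ, λ_min + (k+1)Δλ)` with Δλ = (λ_max − λ_min)/K, and bin *j*
covers `[t₀ + jΔt, t₀ + (j+1)Δt)`. The default axes are 512 channels over
500–760 nm (Δλ = 0.5078125 nm) and 32 bins of 1.5625 ns spanning the 50 ns
period of 20 MHz pulsed excitation. Half-open intervals avoid double counting
at edges; the edge (rather than center) calibration at 500/760 nm is a
convention of this package — the alternative shifts every channel by Δλ/2 and
nothing downstream depends on the choice.

The sensor's per-bin counters are 10-bit; *chaining* merges adjacent bin
pairs (2j, 2j+1) into one 20-bit counter, halving time resolution to extend
dynamic range from 1,023 to 1,048,575 counts per bin. Counts are stored as
unsigned 32-bit words in either mode so both share one HDF5 schema
(`/counts` + attribute groups for axes, sensor and provenance, with an
explicit schema version that readers refuse to guess around).

The instrument reports a sensor time resolution much finer than the
histogram bin width; since the public record does not fix the bin width or
observation window, both are configurable on `TimeAxis`, and the default
spans the full laser period.

## Simulator

The expected count at (y, x, k, j) is

```
Σ_f  w_f(y,x) · β_f · T · E_f(k) · [η(k)/η_peak] · p_f(j)  +  d(k) · T_s / J
```

where `w_f` is the per-pixel mixing weight, `β_f` the fluorophore brightness
(expected *detected* photons per µs dwell at unit weight, referenced to the
peak-efficiency channel), `T` the dwell time in µs (`T_s` in seconds),
`E_f(k)` the Gaussian emission density integrated over channel *k*, `η(k)`
the photon detection efficiency (peak 0.17), `p_f(j)` the decay bin
probability and `d(k)` the dark-count rate in counts/s/channel spread
uniformly over the J bins (dark counts are uncorrelated with the laser).

`p_f(j)` integrates `exp(−t/τ)` convolved with a Gaussian instrument
response over each bin — an exponentially modified Gaussian, evaluated
through survival-function differences to keep full relative precision deep
in the tail — and renormalizes over the observed window. Wrap-around across
the 50 ns period is neglected: for nanosecond lifetimes the truncated mass
is below `exp(−50/τ)` ≈ 10⁻¹⁴–10⁻⁷. The IRF FWHM defaults to 100 ps (the
laser pulse bound, with detector jitter folded into the same Gaussian; the
true pulse shape is not public).

Counts are independent Poisson draws from the expectation. In unchained mode
each bin clips at 2¹⁰ − 1. In chained mode photons are still resolved at the
raw bin width but pairs share one 20-bit counter, so the simulator draws at
raw resolution, merges pairs, and clips the merged bins at 2²⁰ − 1. This
matters: a 1.5 ns decay concentrates ~64% of its photons in the peak 1.5625 ns
bin, so any channel beyond ~1,600 photons saturates a 10-bit counter and
biases tail fits long by ~10% — the bright-peak regime is only faithfully
simulated through the chained path.

The default phantom conditions mirror the acquisition settings used on real
samples: 500 µs dwell (1 ms for tissue), chained readout, a dark-count rate
of 100 counts/s/channel (the sensor's rate is not published; this puts the
expected background at 0.05 counts per pixel-channel at 500 µs, far below
any signal of interest, which is the regime the 10×-background rule
presumes), and a smooth synthetic detection-efficiency curve peaking at 0.17
near 550 nm. What the simulator does **not** model: optical point-spread
blur, SPAD afterpulsing/crosstalk, sub-channel (16-SPAD) nonuniformity,
multi-exponential decays, scattering backgrounds. Tests passing on these
phantoms therefore validate the estimator under Poisson statistics and the
stated forward model, not robustness to those instrument artifacts.

## Correction chain

Order is fixed: **decode chained bins → subtract dark → flat-field**. Dark
counts are additive and efficiency is multiplicative, so the two corrections
only commute when the efficiency curve is flat; the ordered
`corrections_applied` tags make the order auditable and each correction
refuses to run twice.

* `decode_chained` merges pairs (2j, 2j+1) by summation; totals are conserved
  exactly. The merged bin's representative time is the geometric midpoint of
  the union interval: for bin-integrated exponentials the midpoint model is
  exact (the integral over a uniform bin is proportional to the value at its
  center), whereas a count-weighted representative time would be
  data-dependent and stochastic.
* `subtract_dark` removes the expected dark contribution
  `d(k)·T_s/J` per bin, clipping at zero. Clipping keeps the cube
  non-negative but adds a small positive bias (~0.4·√rate per bin) on
  dark-dominated bins; `clip=False` provides an unclipped diagnostic mode in
  which the subtraction is exactly mean-zero on dark-only data, used to
  verify the dark model.
* `flatfield_spectral` divides by the relative efficiency `η(k)/η_peak`.
  Division is the physically meaningful inverse of a multiplicative
  detection probability. Zero-efficiency channels cannot be corrected by
  division and are masked to zero with their indices recorded in provenance.

## Lifetime fitting

Model: `I(t) = A·exp(−t/τ) + B`, least squares over bins from the **peak bin
onward** (tail fit). Starting at the peak sidesteps IRF deconvolution: with a
~100 ps IRF against nanosecond bins, the rising edge lives inside the peak
bin. For a pure exponential the tail model evaluated at bin centers is exact
for bin-integrated data.

The minimizer is variable projection: for fixed τ, the optimal (A, B) solve a
2×2 normal system in closed form, so the residual is a smooth 1-D function of
τ. A 40-point log-spaced grid over `[Δt/20, 50 ns]` brackets the minimum and
55 golden-section iterations refine it to ~10⁻¹² relative — deterministic,
with no data-dependent iteration count, and vectorized over every decay in a
cube simultaneously (a 64×64×64-channel cube fits in ~2 s on one CPU; the
33.6 million candidate fits of a full frame are feasible in minutes). A fit
is invalid (τ reported as 0) when fewer than 3 tail bins are positive, the
amplitude comes out non-positive (e.g. constant input, where the projection
yields A = 0 exactly), or τ pins to a search bound (lifetimes at or beyond
the 50 ns window are unresolvable). Poisson-weighted least squares
(`1/max(counts,1)` variances) is available behind a flag; the default is
unweighted. `chi_square` is the residual sum over the tail divided by
(n_tail − 3); `n_photons` counts the fitted range.

Thresholding: a decay is fitted only where its total channel intensity is at
least `background_multiple` (default 10) times the per-channel background
level **and** at least `absolute_min_counts` (default 200). The background
for the 10× rule is the *expected* dark total per (pixel, channel) at the
cube's dwell time — scattering contributes on the real instrument but has no
model here. The mask is monotone under threshold tightening by construction.

Spectral smoothing: a moving mean of `smoothing_width` channels (default 8,
≈ 4.06 nm at 0.5078 nm/channel) applied across the channel axis of the decay
histograms before thresholding and fitting, with truncated windows at the
spectrum edges (for even widths, the extra channel sits on the
long-wavelength side). Modes: `off`, `full` (whole spectrum, as used for
photon-starved tissue), and the default `edges_only`, which replaces only
the lowest-signal `edge_channels` (default 64) at each end of the spectrum —
the region the filter exists for. The edge extent is this package's choice;
the width of the "wavelength limit" region was never quantified on the
instrument.

ROI summaries average τ per channel over valid pixels only; channels with no
valid pixel are reported as NaN (missing), never 0, and propagate through
ROI differences.

## Rendering and mosaicking

Wavelength→RGB uses a fixed, documented piecewise-linear visible-spectrum
approximation (linear hue segments violet→blue→cyan→green→yellow→red over
380–780 nm with linear intensity tapers below 420 and above 700 nm), chosen
so rendered hues are reproducible bit-exactly and hue angle is monotone over
the sensor range. Spectral color images sum per-channel contributions
`intensity(k)·rgb(center_k)`, normalize to the brightest RGB component, and
set alpha to normalized total intensity; passing external maxima normalizes
tiles against a whole mosaic. Lifetime images map τ through a perceptually
ordered colormap (viridis) over a stated range, with alpha equal to the
normalized intensity or its complement (`invert_alpha`, which brings out
low-count regions); invalid pixels are fully transparent in both modes.

Stitching places tiles on a pure translation grid derived from stage step
and pixel pitch — no registration refinement, matching fixed-stage
acquisition — and averages overlap strips. Overlap is always derived as
`field_of_view − step` (a 600 µm field stepped 0.5 mm overlaps 100 µm),
never taken from a nominal overlap figure. Mosaic-wide normalization to the
brightest pixel precedes rendering.

## Problem sizes and tolerances

The validation suite runs phantoms at 32×32–64×64 pixels × 64 channels —
sizes chosen so the full chain (simulate, correct, fit) completes in seconds
while every surviving decay still carries the ≥200–2,000 photons that put
fitting in the Poisson-dominated regime. Recovery checks require per-region
median lifetimes within 5% of ground truth (measured: < 0.7%); the
noiseless fitter recovers τ to better than 10⁻⁶ relative; the analytic
fitter's residual is checked against an independent dense 3-D grid search
over (A, τ, B) on randomized Poisson decays; and decay bin probabilities are
checked against a brute-force dense-grid convolution at 10⁵ samples/bin.

## Known limitations

* Single-exponential only: in regions with multiple emitting species the
  fitted τ is a model-mismatch average, not a true lifetime. Multi-exponential,
  global and phasor analyses are out of scope for v1.
* The threshold background has no scattering term.
* The wavelength→RGB map is a rendering convention, not colorimetry (no
  CIE observer, no display gamma).
* Stitching trusts stage metadata; there is no cross-correlation alignment.
* The synthetic detection-efficiency curve stands in for the unpublished
  measured sensor response; only its positivity and peak value are relied
  upon.
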