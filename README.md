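# fsflim

A toolkit for **full-spectral fluorescence lifetime imaging (FS-FLIM)** data:
simulation, correction, lifetime fitting and rendering of photon-count cubes
acquired with a confocal-scanned SPAD line sensor that histograms photon
arrival times on-chip in hundreds of spectral channels simultaneously.

An FS-FLIM acquisition produces, for every image pixel, a time-correlated
single-photon-counting (TCSPC) histogram in each of 512 spectral channels
spanning 500–760 nm (≈ 0.5 nm per channel), with 32 time bins per 50 ns laser
period — or 16 bins when counter pairs are *chained* to extend the per-bin
dynamic range from 10 to 20 bits. The central object is the 4-D count cube

```
counts[row, col, spectral_channel, time_bin]   (non-negative integers)
```

The package is aimed at instrument developers and microscopists who need to
(a) prototype and validate FS-FLIM processing chains against synthetic cubes
with known ground truth, and (b) run the standard processing chain on such
cubes: chained-bin decoding, dark-count subtraction, spectral-efficiency
flat-fielding, thresholded per-channel lifetime fitting, spectral false-color
rendering and stage-translation mosaicking.

## The model

Each (pixel, channel) decay histogram is described by a single-exponential
decay plus a constant background,

```
I(t) = A · exp(−t / τ) + B,
```

fitted by least squares over the time bins from the peak bin onward. Fitting
uses variable projection: for any trial τ the optimal (A, B) solve a 2×2
linear system in closed form, so the fit reduces to a deterministic 1-D
search over τ (log-spaced bracket + golden-section refinement), vectorized
over every decay in the cube at once. A lifetime is only fitted where the
channel intensity exceeds both 10× the expected background and an absolute
count floor (200 counts ≈ 10:1 SNR); rejected entries carry τ = 0.

The simulator inverts this pipeline: Gaussian emission spectra ×
IRF-convolved exponential decays × spectral detection efficiency, plus dark
counts, Poisson shot noise and 10-/20-bit counter saturation.

## Worked example

Simulate a two-fluorophore phantom (left half: 560 nm emitter with τ = 1.5 ns;
right half: 690 nm emitter with τ = 3.5 ns), run the correction chain and fit
every surviving decay:

```python
from fsflim.phantoms import recover_phantom_lifetimes

res = recover_phantom_lifetimes(seed=1, rows=64, cols=64, n_channels=64)
print(f"candidate fits : {res['n_candidates']}")
print(f"fits attempted : {res['n_attempted']}")
print(f"valid lifetimes: {res['n_valid']}")
print(f"median tau (left half) : {res['tau_short_median']:.3f} ns  (truth 1.5 ns)")
print(f"median tau (right half): {res['tau_long_median']:.3f} ns  (truth 3.5 ns)")
```

prints

```
candidate fits : 262144
fits attempted : 20300
valid lifetimes: 20300
median tau (left half) : 1.509 ns  (truth 1.5 ns)
median tau (right half): 3.524 ns  (truth 3.5 ns)
```

262,144 candidate decays (64 × 64 pixels × 64 channels) pass through the
threshold rules; the 20,300 bright enough to fit are all fitted validly, and
the per-region median lifetimes land within 0.7% of the simulated truth.

The same pipeline is available from the shell:

```
fsflim simulate --scene scene.yaml --dwell-us 500 --seed 1 --chained -o cube.h5
fsflim correct cube.h5 --dark --flatfield -o corr.h5
fsflim fit corr.h5 --bg-multiple 10 --min-counts 200 -o fit.h5
fsflim render fit.h5 --channel-nm 560 -o lifetime_560nm.png
fsflim stitch --grid 2x10 --step-um 500 --fov-um 600 tiles/*.h5 -o mosaic.png
```

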