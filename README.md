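# flimphasor

Phasor-plot and multi-exponential analysis of time-domain FLIM/TCSPC data,
built for label-free metabolic readouts: the balance of free NADH (short
lifetime τ₁ ≈ 0.3–0.8 ns) versus protein-bound NADH (long lifetime
τ₂ ≈ 1–6.5 ns) in living samples reports glycolysis versus oxidative
phosphorylation, and shifts in that balance can be read non-invasively from
fluorescence decay histograms.

It is aimed at microscopists and image analysts who have per-pixel TCSPC
histograms (512 × 512 × 64-channel time stacks or similar) and want either
or both of:

- **the phasor route** — each pixel's decay is Fourier-transformed at a
  harmonic ω = 2πk/T of the laser repetition rate into coordinates
  G = Σ I cos(ωt)/Σ I, S = Σ I sin(ωt)/Σ I.  Mono-exponential decays fall
  on the universal semicircle g² + s² = g; mixed pixels fall on the chord
  between their component points.  A total-least-squares line through the
  cloud, intersected with the circle, yields τ₁ and τ₂ via τ = s/(gω); the
  lever rule on the projected mean yields the short-lifetime contribution
  α₁ᵖʰᵃˢᵒʳ; a 95% confidence ellipse (axis ratio a/b) quantifies whether
  the cloud is mono-exponential-like (a/b ≈ 1) or spread (a/b ≫ 1).  No
  iterative fitting and no prior choice of component count.
- **the fitting route (MEDF)** — per-pixel weighted least squares of
  I(t) = C + α₁e^{−t/τ₁} + α₂e^{−t/τ₂} (optionally IRF-convolved), with
  reduced χ² goodness of fit, reproducing the conventional SPCImage-style
  analysis for cross-checking the phasor results.

A seeded TCSPC simulator (Poisson photon noise, Gaussian IRF, periodic
wrap, spatial patterns) provides ground-truth data for validation, and a
CLI (`flimphasor simulate | phasor | medf | compare`) wraps the library.

## Worked example

Simulate an NADH-like two-component measurement, run the phasor pipeline
(calibrated against a 2 ns reference), and cross-check with the fitter:

```python
from flimphasor import *

spec = SyntheticSpec(
    components=((750.0, 0.30), (2900.0, 0.70)),   # (tau_ps, intensity fraction)
    photons_per_pixel=1e4, shape=(64, 64),
    spatial_pattern="two-region", fraction_delta=0.05, seed=42,
)
cube, truth = simulate_cube(spec)

ps = PhasorSettings(harmonic=1, window_fraction=1.0, baseline_subtraction=False)
reference = reference_fixture(2000.0, cube.settings)
cloud = calibrated_transform(cube, reference, 2000.0, ps)
result = analyze_cloud(cloud)
print(f"tau1 (free)   : {result.pair.tau1:7.1f} ps")
print(f"tau2 (bound)  : {result.pair.tau2:7.1f} ps")
print(f"alpha1 (lever): {result.contribution.alpha1:7.4f}")
print(f"ellipse a/b   : {result.ellipse.ratio:7.2f}")

irf = IRF.from_gaussian(250.0, cube.settings)
agg = fit_cube(cube, irf, 0.30, wrap=True, pixel_limit=500).aggregate()
print(f"alpha1 (MEDF) : {agg['alpha1_medf_mean']:7.4f} +/- {agg['alpha1_medf_sd']:.4f}")
```

prints

```
tau1 (free)   :   766.0 ps
tau2 (bound)  :  2913.3 ps
alpha1 (lever):  0.3051
ellipse a/b   :    6.84
alpha1 (MEDF) :  0.6070 +/- 0.0635
```

The chord intersections recover the true lifetimes (750 / 2900 ps) within
~2%, and the lever fraction recovers the true short-component intensity
fraction (0.30) within half a point.  The fitted amplitude fraction 0.607
is a *different* quantity (amplitude, not intensity, fraction; truth
0.619); converting it via f₁ = α₁τ₁/(α₁τ₁ + α₂τ₂) reproduces the lever
value — the consistency check exposed as `flimphasor compare`.

The elongated ellipse (a/b ≈ 6.8) flags genuine two-component spread; a
mono-exponential dye cube instead clusters to a point (a/b near 1) and
`analyze_cloud` then reports the single lifetime of the mean phasor.

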