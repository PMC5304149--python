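# Methods

## The measurement and the two analysis branches

A time-domain FLIM measurement records, for every image pixel, a TCSPC
histogram of photon arrival times over one laser repetition period `T`
(default 12 500 ps, the 80 MHz Ti:Sapphire period) discretised into
`n_channels` bins (default 64).  The signal of interest is NADH
autofluorescence: free NADH decays with a short lifetime τ₁ (≈0.3–0.8 ns),
protein-bound NADH with a long lifetime τ₂ (≈1–6.5 ns), and the balance of
the two fractions reports the balance of glycolysis versus oxidative
phosphorylation.

flimphasor implements the two standard routes to (τ₁, τ₂, α₁):

1. **Phasor analysis** (`model`, `geometry`).  Each pixel's histogram is
   mapped to

       g = Σ_w I(tᵢ) cos(ω tᵢ) / Σ_w I(tᵢ),
       s = Σ_w I(tᵢ) sin(ω tᵢ) / Σ_w I(tᵢ),

   with ω = 2πk/T for harmonic k, times at channel centres measured from
   the window start, and the sum over a configurable fraction of the
   period.  Mono-exponential decays lie on the universal semicircle
   g² + s² = g; two-component pixels lie on the chord between their
   component points, splitting it in proportion to the components'
   fractional intensities.  A total-least-squares line (principal axis of
   the centred covariance — the exact orthogonal-regression solution, since
   shot noise perturbs G and S alike) is intersected with the circle to
   obtain the component points and, via τ = s/(gω), the lifetimes; the
   orthogonal projection of the unweighted mean phasor onto the chord gives
   the lever fraction α₁ (0 at the long-lifetime intersection, 1 at the
   short).  A 95% confidence ellipse (semi-axes √(λ·q) from the covariance
   eigenvalues, q the 2-dof χ² quantile 5.991) summarises cloud shape; an
   axis ratio a/b near 1 marks a mono-exponential-like cluster.

2. **Multi-exponential decay fitting** (`medf`).  Weighted nonlinear least
   squares of `C + a₁ e^{-t/τ₁} + a₂ e^{-t/τ₂}` (optionally convolved with
   the IRF), Poisson/Neyman weights `max(count, 1)`, trust-region solver
   with an analytic Jacobian and three deterministic starts spanning the
   physical lifetime range ((300, 2000), (600, 3000), (800, 5000) ps;
   bounds 10–10 000 ps).  A start is accepted early when its reduced χ² is
   already below 1.5.  α₁ = a₁/(a₁+a₂) is reported after undoing the
   channel-integration factor, so amplitude fractions refer to the
   continuous decay and match the simulator's ground-truth definition.

The two α₁ values are *not* the same quantity: the lever fraction is an
intensity fraction, the fit's an amplitude fraction.  They are linked by
f₁ = α₁τ₁ / (α₁τ₁ + α₂τ₂), and this conversion is asserted on synthetic
data (and exposed as the `compare` CLI command).

## Windows, harmonics and why the pairing matters

The transform window is a fraction of the period: k = 2 with the first
half, or k = 4 with the first quarter, each covers exactly one cycle of the
transform frequency.  For a *continuous* exponential starting at the window
origin, the truncated transform over exactly one cycle equals the
full-period closed form g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²) — the reason
these pairings are used at all.  Two residual effects remain and are
handled explicitly:

- **Discretisation.**  With 64 channels the sampled transform of a wrapped
  exponential has the exact geometric-series form
  `P = e^{iωΔ/2}(1−r)/(1−r e^{iωΔ})`, `r = e^{−Δ/τ}`
  (`mono_exponential_phasor_sampled`), which deviates from the continuous
  closed form by up to ~0.02 in the plane.  The transform is left
  uncorrected by default; the sampled form is the analytic reference for
  simulations and the documented tolerance for on-circle checks
  (10⁻³ densely sampled, 0.02 at 64 channels).

- **Fraction-window lever distortion.**  Over a fractional window the lever
  weights are the *windowed* intensities: the long component's tail beyond
  the window is excluded, inflating the apparent short fraction (≈ +2.4
  points at f₁ = 0.30 with the half-period window for 750/2900 ps).  The
  package default remains the conventional k = 2 / half-period for cell
  data (where α₁ is used comparatively, before vs after treatment and the
  distortion cancels in the difference); quantitative recovery of total
  intensity fractions uses k = 1 over the full period with wrap, where the
  windowed and total fractions coincide.

The window starts at the pooled-intensity peak by default (configurable to
a fixed channel): the rising edge of the IRF is thereby excluded and the
decay is exponential from the window origin on.  Baseline subtraction (the
pre-rise minimum per pixel, clipped at zero) is on by default, mirroring
the offset rule of the fitting branch.

## Calibration

IRF convolution multiplies full-period phasors by a common complex factor,
so a reference measurement of known lifetime calibrates the plane: every
point is multiplied by the factor that maps the reference's mean phasor
onto its closed-form circle position.  Three conventions matter and are
fixed here:

- the reference mean is **intensity-weighted** (the phasor of the pooled
  reference decay), which is free of the per-pixel ratio bias of low-count
  pixels;
- cube and reference are transformed with the **same window-start
  channel** (`calibrated_transform` pins the measurement's pooled peak on
  both); a one-channel mismatch would leave an uncorrected relative phase
  of ωΔ — nearly 0.4 rad at k = 4;
- for fractional windows the IRF does not factor *exactly* out of the
  truncated transform, so the residual depends on how similar the
  reference decay is to the analyte; the default reference lifetime is
  2.0 ns, near the analytes of interest.  (With the full-period window the
  factorisation is exact and the reference lifetime is uncritical.)

## The simulator and what passing tests show

`synth` generates decay cubes with known truth: components specified by
*intensity fraction* (the quantity the lever measures; amplitude fractions
αᵢ ∝ fᵢ/τᵢ are derived into the ground-truth record), channel-integrated
profiles with optional periodic wrap (the steady state of pulsed
excitation), a Gaussian IRF (default FWHM 250 ps, typical of two-photon
TCSPC; peak at four channel widths so a pre-rise region exists), constant
background, and per-pixel Poisson noise under a fixed seed
(bit-reproducible).  Spatial patterns: `uniform`; `two-region` (the short
fraction split ±δ, default 0.05, across the image halves — giving phasor
clouds that actually spread along the chord, as tissue heterogeneity does);
`ring` (a bright annulus, a crude luminal-cyst section, for threshold
tests).

Not modelled: detector after-pulsing, pile-up, spectral bleed-through,
spatially varying IRF, scattering with depth.  Passing tests therefore
demonstrate correctness of the estimators under Poisson statistics with a
known IRF — not robustness to instrument pathologies.

Default photon scales: 10⁴ photons/pixel for NADH-like recovery runs;
8 000 photons/pixel over 64×64 for the coumarin-6 validation fixture
(≈3.3×10⁷ photons, a bright dye solution at ~180 kcounts/s for 3 min) —
at harmonic 4 a 2.5 ns decay sits at g ≈ 0.04, where the lifetime readout
amplifies shot noise ~25-fold, so a dye-solution photon budget is what
makes a ±0.05 ns validation meaningful.  The metabolic-shift fixture uses
2 000 photons/pixel on 32×32 (16×16 in the replicate suite), enough for the
sign of a 6-point fraction shift to be essentially always resolved.

## Numerical and design choices

- **Offset policy (fitting).**  `estimate_offset` returns the pre-rise
  minimum (global minimum if the peak is in channel 0).  As the fixed C of
  the fit it is the default only for the *aperiodic* model; the periodic
  (wrap) model already carries the pre-excitation floor in the wrapped
  exponential, and subtracting it again as a constant badly biases the fit
  (reduced χ² ~20 on noiseless data).  C can always be given explicitly or
  floated as a fifth bounded parameter.
- **Lever orientation.**  α₁ grows toward the short-lifetime intersection,
  the orientation consistent with the direction of metabolic shifts and
  with the amplitude-fit conversion; the opposite ("distance from τ₁")
  reading is available as `orientation="literal"`.
- **Mono fallback.**  `analyze_cloud` falls back to a single lifetime (of
  the intensity-weighted mean phasor) when the ellipse ratio is below 1.2
  or the TLS direction is ambiguous: a compact cluster does not constrain
  a chord.  The threshold sits above the ratio observed for
  dye-like clusters (~1.1) and far below that of heterogeneous
  two-component clouds (>2 in all simulated conditions).
- **Degenerate inputs.**  Empty windows, sub-threshold cubes, coincident or
  isotropic clouds, tangent or non-intersecting lines, and singular
  covariances each raise a dedicated exception; the pipeline wrapper tags
  failures with the stage that raised them.
- **Ties and signs.**  The TLS direction is sign-normalised (g-component
  ≥ 0); intersections are labelled by descending g, which orders lifetimes
  ascending since lifetime increases counter-clockwise along the
  semicircle; fitted lifetime pairs are swap-sorted after convergence.
- **Intersections with g ≤ 0** are reported as infinite lifetime rather
  than a spurious number; the s < 0 half-plane is excluded as unphysical.

## Problem sizes

The test suite simulates at most 64×64×64 cubes; per-pixel fitting of such
a cube takes ~15 s (three-start trust-region fits at ~3 ms each, early
acceptance usually leaving one start).  The replicate suites use 16×16
cubes.  `fit_cube(pixel_limit=…)` fits a deterministic evenly spaced pixel
subset when only the aggregate is needed.

## Known limitations

- Two components only in the fitter (the NADH use case); no global
  multi-pixel fitting; no >2-component phasor unmixing.
- α₁ is a single per-image number (line + lever per cloud), not a per-pixel
  map from phasor coordinates.
- SPCImage's proprietary binning/weighting/IRF-shift internals are not
  replicated; equivalence claims are against synthetic ground truth only.
- Vendor `.sdt` reading requires the optional `sdtfile` dependency and is
  best-effort on axis metadata.
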