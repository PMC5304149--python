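"""TCSPC simulator: decay cubes with known ground truth.

Stands in for the microscope in every test: mono- or bi-exponential decays
(the coumarin-6 validation dye at 2.5 ns; free/bound NADH mixtures in the
0.3-0.8 ns / 1-6.5 ns literature ranges), convolved with a Gaussian
instrument response, over a repetition period with optional periodic wrap,
plus a constant background, with per-pixel Poisson photon statistics and
simple spatial intensity/fraction patterns.  Components are specified by
*intensity fraction* — the quantity the phasor lever rule measures — and the
corresponding MEDF amplitude fractions (``alpha_i`` proportional to
``f_i / tau_i``) are reported in the ground-truth record so both analysis
branches have an unambiguous truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError
from .model import AcquisitionSettings, DecayCube

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "ideal_decay_curve",
    "simulate_cube",
    "coumarin_fixture",
    "reference_fixture",
    "metabolic_shift_fixture",
]

_PATTERNS = ("uniform", "two-region", "ring")

#: Default Gaussian IRF width in ps — typical for a two-photon TCSPC system.
DEFAULT_IRF_FWHM_PS = 250.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of a simulated measurement.

    ``components`` is a sequence of ``(tau_ps, intensity_fraction)`` pairs
    with fractions summing to one.  ``fraction_delta`` is the two-region
    contrast: the first component's fraction is lowered by delta in the left
    half of the image and raised by delta in the right half.
    """

    components: tuple[tuple[float, float], ...]
    photons_per_pixel: float = 1e4
    irf_fwhm: float = DEFAULT_IRF_FWHM_PS
    background_rate: float = 0.0
    shape: tuple[int, int] = (64, 64)
    spatial_pattern: str = "uniform"
    fraction_delta: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        comps = tuple((float(t), float(f)) for t, f in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise InvalidSpecError("at least one component is required")
        if any(t <= 0 for t, _ in comps):
            raise InvalidSpecError("component lifetimes must be positive")
        if any(f < 0 for _, f in comps):
            raise InvalidSpecError("intensity fractions must be non-negative")
        if abs(sum(f for _, f in comps) - 1.0) > 1e-12:
            raise InvalidSpecError("intensity fractions must sum to 1")
        if self.photons_per_pixel <= 0:
            raise InvalidSpecError("photon budget must be positive")
        if self.irf_fwhm < 0 or self.background_rate < 0:
            raise InvalidSpecError("rates must be non-negative")
        if self.spatial_pattern not in _PATTERNS:
            raise InvalidSpecError(
                f"spatial_pattern must be one of {_PATTERNS}"
            )
        if self.spatial_pattern == "two-region" and len(comps) != 2:
            raise InvalidSpecError("two-region patterns require 2 components")

    @property
    def amplitude_fractions(self) -> tuple[float, ...]:
        """MEDF-style amplitude fractions, ``alpha_i ~ f_i / tau_i``."""
        raw = [f / t for t, f in self.components]
        total = sum(raw)
        return tuple(r / total for r in raw)


@dataclass(frozen=True)
class GroundTruth:
    """Per-pixel truth record saved alongside a simulated cube."""

    spec: SyntheticSpec
    f1_map: np.ndarray  # per-pixel intensity fraction of component 1
    budget_map: np.ndarray  # per-pixel expected photon count (signal only)

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.spec.components)

    @property
    def mean_f1(self) -> float:
        return float(self.f1_map.mean())

    def alpha1_for(self, f1: float) -> float:
        """Amplitude fraction of component 1 at intensity fraction ``f1``."""
        taus = self.taus
        if len(taus) < 2:
            return 1.0
        a1 = f1 / taus[0]
        a2 = (1.0 - f1) / taus[1]
        return a1 / (a1 + a2)

    @property
    def mean_alpha1(self) -> float:
        return float(np.mean([self.alpha1_for(f) for f in self.f1_map.ravel()]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "components": list(self.spec.components),
                "amplitude_fractions": list(self.spec.amplitude_fractions),
                "photons_per_pixel": self.spec.photons_per_pixel,
                "irf_fwhm_ps": self.spec.irf_fwhm,
                "background_rate": self.spec.background_rate,
                "shape": list(self.spec.shape),
                "spatial_pattern": self.spec.spatial_pattern,
                "seed": self.spec.seed,
                "mean_f1": self.mean_f1,
                "mean_alpha1": self.mean_alpha1,
            },
            indent=2,
        )


def _gaussian_irf_profile(
    settings: AcquisitionSettings, fwhm: float, peak_ps: float
) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t = settings.channel_times
    profile = np.exp(-0.5 * ((t - peak_ps) / sigma) ** 2)
    return profile / profile.sum()


def _component_profile(
    tau: float, settings: AcquisitionSettings, wrap: bool
) -> np.ndarray:
    """Channel-integrated exponential, normalised to unit recorded intensity.

    With wrap the decay is the steady-state periodic signal (every earlier
    pulse's tail folded in), which over one period is again proportional to
    ``exp(-t / tau)``.
    """
    dt = settings.channel_width
    edges = np.arange(settings.n_channels + 1) * dt
    profile = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    # wrap rescales every channel equally, so unit normalisation absorbs it
    return profile / profile.sum()


def ideal_decay_curve(
    components,
    settings: AcquisitionSettings | None = None,
    *,
    irf_fwhm: float = 0.0,
    irf_peak_ps: float | None = None,
    background_rate: float = 0.0,
    photons: float = 1.0,
    wrap: bool = True,
) -> np.ndarray:
    """Expected channel intensities of a multi-component decay.

    The intensity-normalised component profiles are mixed by their intensity
    fractions, convolved with a Gaussian IRF of the given FWHM (0 = ideal
    instrument; circular convolution under wrap), scaled to the photon
    budget and offset by a constant background per channel.  The returned
    curve sums exactly to ``photons + background_rate * n_channels``.
    """
    settings = settings or AcquisitionSettings()
    comps = tuple((float(t), float(f)) for t, f in components)
    if any(t <= 0 for t, _ in comps):
        raise InvalidSpecError("component lifetimes must be positive")
    total_f = sum(f for _, f in comps)
    if total_f <= 0:
        raise InvalidSpecError("intensity fractions must have positive sum")
    mixture = np.zeros(settings.n_channels)
    for tau, f in comps:
        mixture += (f / total_f) * _component_profile(tau, settings, wrap)
    if irf_fwhm > 0:
        if irf_peak_ps is None:
            # same placement rule as IRF.from_gaussian, so a fitted model IRF
            # aligns with simulated data by default
            irf_peak_ps = 4.0 * settings.channel_width
        irf = _gaussian_irf_profile(settings, irf_fwhm, irf_peak_ps)
        if wrap:
            mixture = np.real(np.fft.ifft(np.fft.fft(mixture) * np.fft.fft(irf)))
        else:
            mixture = np.convolve(mixture, irf)[: settings.n_channels]
        mixture = np.clip(mixture, 0.0, None)
        mixture /= mixture.sum()
    return photons * mixture + background_rate


def _pattern_maps(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (f1, budget-scale) maps for the requested spatial pattern."""
    rows, cols = spec.shape
    f1_nominal = spec.components[0][1]
    f1 = np.full(spec.shape, f1_nominal)
    scale = np.ones(spec.shape)
    if spec.spatial_pattern == "two-region":
        half = cols // 2
        f1[:, :half] = f1_nominal - spec.fraction_delta
        f1[:, half:] = f1_nominal + spec.fraction_delta
        if (f1 < 0).any() or (f1 > 1).any():
            raise InvalidSpecError("fraction_delta pushes f1 outside [0, 1]")
    elif spec.spatial_pattern == "ring":
        # bright annulus on a dim background, a crude luminal-cyst section
        r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        radius = np.hypot(rr - r0, cc - c0) / (min(rows, cols) / 2.0)
        annulus = (radius >= 0.5) & (radius <= 0.9)
        scale = np.where(annulus, 1.0, 0.05)
    return f1, scale


def simulate_cube(
    spec: SyntheticSpec, settings: AcquisitionSettings | None = None
) -> tuple[DecayCube, GroundTruth]:
    """Poisson-noised decay cube for a synthetic spec, with its ground truth.

    Deterministic for a fixed seed: the same spec yields a bit-identical
    cube.  Only Poisson photon noise is modelled (no after-pulsing or
    pile-up).
    """
    settings = settings or AcquisitionSettings()
    rng = np.random.default_rng(spec.seed)
    f1_map, scale_map = _pattern_maps(spec)
    budget_map = spec.photons_per_pixel * scale_map

    taus = [t for t, _ in spec.components]
    expected = np.empty((*spec.shape, settings.n_channels))
    # group identical (f1, scale) pixels so each distinct curve is built once
    combos = {}
    for idx in np.ndindex(spec.shape):
        key = (f1_map[idx], scale_map[idx])
        combos.setdefault(key, []).append(idx)
    for (f1, scale), indices in combos.items():
        if len(taus) == 1:
            comps = [(taus[0], 1.0)]
        else:
            comps = [(taus[0], f1), (taus[1], 1.0 - f1)]
        curve = ideal_decay_curve(
            comps, settings,
            irf_fwhm=spec.irf_fwhm,
            background_rate=spec.background_rate,
            photons=spec.photons_per_pixel * scale,
        )
        for idx in indices:
            expected[idx] = curve
    counts = rng.poisson(expected).astype(np.int64)
    cube = DecayCube(counts=counts, settings=settings)
    truth = GroundTruth(spec=spec, f1_map=f1_map, budget_map=budget_map)
    return cube, truth


#: Literature mono-exponential lifetime of coumarin 6, in ps.
COUMARIN_TAU_PS = 2500.0


def coumarin_fixture(
    settings: AcquisitionSettings | None = None,
    *,
    photons_per_pixel: float = 8000.0,
    shape: tuple[int, int] = (64, 64),
    irf_fwhm: float = DEFAULT_IRF_FWHM_PS,
    seed: int = 7,
) -> DecayCube:
    """Mono-exponential validation cube mimicking a coumarin-6 solution.

    Defaults give ~3e7 total photons over a 64 x 64 field (about 180
    kcounts/s over a 3-minute acquisition) — the photon scale of a bright
    dye-solution validation measurement, far above the 1e6-photon floor a
    lifetime validation needs.
    """
    spec = SyntheticSpec(
        components=((COUMARIN_TAU_PS, 1.0),),
        photons_per_pixel=photons_per_pixel,
        irf_fwhm=irf_fwhm,
        shape=shape,
        seed=seed,
    )
    cube, _ = simulate_cube(spec, settings)
    return cube


def reference_fixture(
    tau_ps: float = 2000.0,
    settings: AcquisitionSettings | None = None,
    *,
    photons_per_pixel: float = 8000.0,
    shape: tuple[int, int] = (64, 64),
    irf_fwhm: float = DEFAULT_IRF_FWHM_PS,
    seed: int = 11,
) -> DecayCube:
    """Mono-exponential reference cube of known lifetime for calibration.

    The default reference lifetime (2 ns) sits near the analytes of
    interest: for fractional-period windows the transform of an
    IRF-convolved signal is not exactly multiplicative in the IRF, so the
    closer the reference decay is to the analyte, the more completely the
    calibration cancels the residual truncation error.
    """
    spec = SyntheticSpec(
        components=((tau_ps, 1.0),),
        photons_per_pixel=photons_per_pixel,
        irf_fwhm=irf_fwhm,
        shape=shape,
        seed=seed,
    )
    cube, _ = simulate_cube(spec, settings)
    return cube


def metabolic_shift_fixture(
    f1_before: float,
    f1_after: float,
    *,
    tau1: float = 750.0,
    tau2: float = 2900.0,
    photons_per_pixel: float = 2000.0,
    shape: tuple[int, int] = (32, 32),
    irf_fwhm: float = DEFAULT_IRF_FWHM_PS,
    fraction_delta: float = 0.05,
    seed: int = 0,
    settings: AcquisitionSettings | None = None,
) -> tuple[DecayCube, DecayCube, GroundTruth, GroundTruth]:
    """Paired before/after cubes sharing lifetimes, differing in short
    fraction — a synthetic analogue of a chemically induced metabolic shift.

    Each cube uses a two-region fraction pattern (so the phasor cloud spreads
    along the chord and constrains a line); the region means are
    ``f1_before`` and ``f1_after``.  Independent child seeds are derived
    deterministically from ``seed``.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    cubes = []
    truths = []
    for f1, child in zip((f1_before, f1_after), child_seeds):
        spec = SyntheticSpec(
            components=((tau1, f1), (tau2, 1.0 - f1)),
            photons_per_pixel=photons_per_pixel,
            irf_fwhm=irf_fwhm,
            shape=shape,
            spatial_pattern="two-region",
            fraction_delta=fraction_delta,
            seed=int(child),
        )
        cube, truth = simulate_cube(spec, settings)
        cubes.append(cube)
        truths.append(truth)
    return cubes[0], cubes[1], truths[0], truths[1]
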