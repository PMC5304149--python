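"""Domain types for TCSPC decay data and the per-pixel phasor transform.

A TCSPC measurement is a 3D histogram of photon arrival times: one decay
curve of ``n_channels`` time bins per image pixel, recorded over one laser
repetition period ``T``.  The phasor transform maps each pixel's decay to a
point in the G-S plane,

    g = sum_w I(t_i) cos(w t_i) / sum_w I(t_i)
    s = sum_w I(t_i) sin(w t_i) / sum_w I(t_i)

with angular frequency ``w = 2 pi k / T`` for harmonic ``k``, the times
``t_i`` taken at channel centres measured from the window start, and the sum
running over a configurable fraction of the period.  Mono-exponential decays
fall on the universal semicircle ``g**2 + s**2 = g``; mixtures fall inside it
on the chord between their component points, dividing the chord in proportion
to the components' fractional intensities (the lever rule exploited in
:mod:`flimphasor.geometry`).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    CalibrationError,
    EmptyCloudError,
    EmptyPixelError,
    InvalidInputError,
)

__all__ = [
    "AcquisitionSettings",
    "PhasorSettings",
    "DecayCube",
    "PhasorCloud",
    "pixel_phasor",
    "transform_cube",
    "mono_exponential_phasor",
    "mono_exponential_phasor_sampled",
    "lifetime_from_point",
    "calibrate_cloud",
    "calibrated_transform",
]

#: Repetition period of an 80 MHz Ti:Sapphire oscillator, in ps.  A default,
#: never an assumption: readers must supply the real period of the instrument.
DEFAULT_REPETITION_PERIOD_PS = 12_500.0
DEFAULT_N_CHANNELS = 64


@dataclass(frozen=True)
class AcquisitionSettings:
    """Timing metadata of a TCSPC acquisition.

    Parameters
    ----------
    repetition_period
        Laser repetition period ``T`` in ps (12 500 ps for an 80 MHz source).
    n_channels
        Number of time channels per pixel.
    channel_width
        Width of one time channel in ps.  Defaults to ``T / n_channels`` so
        the channels tile the full period.
    excitation_wavelength
        Optional, metadata only (nm).
    """

    repetition_period: float = DEFAULT_REPETITION_PERIOD_PS
    n_channels: int = DEFAULT_N_CHANNELS
    channel_width: float | None = None
    excitation_wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.channel_width is None:
            object.__setattr__(
                self, "channel_width", self.repetition_period / self.n_channels
            )
        if self.repetition_period <= 0 or self.channel_width <= 0:
            raise InvalidInputError("durations must be strictly positive")
        if self.n_channels < 1:
            raise InvalidInputError("n_channels must be a positive integer")
        span = self.n_channels * self.channel_width
        if span > self.repetition_period * (1 + 1e-9):
            raise InvalidInputError(
                f"measurement window ({span} ps) exceeds the repetition "
                f"period ({self.repetition_period} ps)"
            )

    @property
    def channel_times(self) -> np.ndarray:
        """Channel-centre times in ps, measured from the start of the record."""
        return (np.arange(self.n_channels) + 0.5) * self.channel_width

    @property
    def spans_full_period(self) -> bool:
        """Whether the channels tile the whole repetition period (half a
        channel of slack allowed); only then may a window wrap around."""
        return (
            abs(self.n_channels * self.channel_width - self.repetition_period)
            < 0.5 * self.channel_width
        )

    def omega(self, harmonic: int = 1) -> float:
        """Angular transform frequency ``2 pi k / T`` in rad/ps."""
        if harmonic < 1:
            raise InvalidInputError("harmonic must be >= 1")
        return 2.0 * math.pi * harmonic / self.repetition_period


@dataclass(frozen=True)
class PhasorSettings:
    """Parameters of the phasor transform.

    ``harmonic`` and ``window_fraction`` are normally paired so that the
    window covers an integer number of cycles of the transform frequency
    (k = 2 with half the period, k = 4 with a quarter): over exactly one
    cycle the truncated transform of an exponential equals its full-period
    closed form.  ``window_start`` is either a fixed channel index or
    ``"peak"`` (start at the pooled-intensity maximum, i.e. the decay onset).
    ``threshold_fraction`` drops pixels dimmer than that fraction of the
    brightest pixel; 0.30 is the conventional SPCImage-style cut.
    """

    harmonic: int = 2
    window_fraction: float = 0.5
    window_start: int | str = "peak"
    threshold_fraction: float = 0.30
    baseline_subtraction: bool = True

    def __post_init__(self) -> None:
        if self.harmonic < 1:
            raise InvalidInputError("harmonic must be >= 1")
        if not (0.0 < self.window_fraction <= 1.0):
            raise InvalidInputError("window_fraction must lie in (0, 1]")
        if not (0.0 <= self.threshold_fraction < 1.0):
            raise InvalidInputError("threshold_fraction must lie in [0, 1)")
        if isinstance(self.window_start, str) and self.window_start != "peak":
            raise InvalidInputError(
                "window_start must be a channel index or 'peak'"
            )

    # -- plain-text config dialect (key = value) ---------------------------
    def to_config(self) -> str:
        lines = [
            f"harmonic = {self.harmonic}",
            f"window_fraction = {self.window_fraction}",
            f"window_start = {self.window_start}",
            f"threshold_fraction = {self.threshold_fraction}",
            f"baseline_subtraction = {str(self.baseline_subtraction).lower()}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "PhasorSettings":
        kwargs: dict = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidInputError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "harmonic":
                kwargs[key] = int(value)
            elif key in ("window_fraction", "threshold_fraction"):
                kwargs[key] = float(value)
            elif key == "window_start":
                kwargs[key] = value if value == "peak" else int(value)
            elif key == "baseline_subtraction":
                kwargs[key] = value.lower() in ("true", "1", "yes", "on")
            else:
                raise InvalidInputError(f"unknown config key: {key!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class DecayCube:
    """A 3D grid of photon counts ``[row, col, channel]`` with its timing."""

    counts: np.ndarray
    settings: AcquisitionSettings

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise InvalidInputError(
                f"counts must be 3D [row, col, channel], got ndim={counts.ndim}"
            )
        if counts.shape[2] != self.settings.n_channels:
            raise InvalidInputError(
                f"cube has {counts.shape[2]} channels but settings declare "
                f"{self.settings.n_channels}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise InvalidInputError("photon counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise InvalidInputError("photon counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def intensity_image(self) -> np.ndarray:
        """Per-pixel total photon count (sum over time channels)."""
        return self.counts.sum(axis=2)

    @property
    def max_intensity(self) -> int:
        return int(self.intensity_image.max())

    def pixel_decay(self, row: int, col: int) -> np.ndarray:
        return self.counts[row, col, :]

    def pooled_decay(self) -> np.ndarray:
        """Decay summed over all pixels (used to locate the global peak)."""
        return self.counts.sum(axis=(0, 1))


@dataclass(frozen=True)
class PhasorCloud:
    """Per-pixel phasor coordinates of the above-threshold pixels of a cube."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    omega: float
    source_settings: PhasorSettings | None = None

    def __post_init__(self) -> None:
        for name in ("g", "s", "intensity"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=int).reshape(-1, 2))
        n = len(self.g)
        if not (len(self.s) == len(self.intensity) == len(self.pixels) == n):
            raise InvalidInputError("cloud component arrays must share one length")
        if self.omega <= 0:
            raise InvalidInputError("omega must be positive")

    def __len__(self) -> int:
        return len(self.g)

    @classmethod
    def from_points(
        cls,
        g: Sequence[float],
        s: Sequence[float],
        omega: float,
        intensity: Sequence[float] | None = None,
    ) -> "PhasorCloud":
        """Build a cloud directly from G-S coordinates (tests, simulations)."""
        g = np.asarray(g, dtype=float)
        s = np.asarray(s, dtype=float)
        if intensity is None:
            intensity = np.ones_like(g)
        pixels = np.column_stack([np.arange(len(g)), np.zeros(len(g), dtype=int)])
        return cls(g=g, s=s, intensity=np.asarray(intensity, float),
                   pixels=pixels, omega=omega)

    def mean_phasor(self, weighted: bool = False) -> tuple[float, float]:
        """Mean of the cloud.

        Unweighted by default (every thresholded pixel counts once — the
        convention used for the lever-rule projection).  ``weighted=True``
        returns the intensity-weighted mean, equivalent to the phasor of the
        pooled decay: statistically optimal for a spatially uniform emitter
        and free of the per-pixel ratio bias of low-count pixels, hence used
        for calibration references and single-lifetime readouts.
        """
        if len(self) == 0:
            raise EmptyCloudError("cannot average an empty cloud")
        if weighted:
            w = self.intensity / self.intensity.sum()
            return float((self.g * w).sum()), float((self.s * w).sum())
        return float(self.g.mean()), float(self.s.mean())

    def outside_semicircle(self, tol: float = 0.0) -> np.ndarray:
        """Mask of points lying outside the universal semicircle by > tol.

        Physically meaningful decays satisfy ``g**2 + s**2 <= g`` and
        ``s >= 0``; shot noise pushes points past the boundary, so violations
        are flagged, never dropped.
        """
        radial = np.hypot(self.g - 0.5, self.s) - 0.5
        return (radial > tol) | (self.s < -tol)


# ---------------------------------------------------------------------------
# window resolution helpers
# ---------------------------------------------------------------------------

def _pre_rise_offset(decay: np.ndarray) -> float:
    """Baseline estimate: the minimum count before the rising edge.

    Falls back to the global minimum when the peak sits in channel 0 (no
    pre-rise region recorded).
    """
    peak = int(np.argmax(decay))
    if peak == 0:
        return float(decay.min())
    return float(decay[:peak].min())


def _window_length(settings: AcquisitionSettings, phasor: PhasorSettings) -> int:
    n = int(round(phasor.window_fraction * settings.repetition_period
                  / settings.channel_width))
    return max(1, min(n, settings.n_channels))


def _window_indices(
    settings: AcquisitionSettings, phasor: PhasorSettings, start: int
) -> np.ndarray:
    n_win = _window_length(settings, phasor)
    idx = start + np.arange(n_win)
    if settings.spans_full_period:
        # channels tile the period, so the window may wrap around
        return idx % settings.n_channels
    return idx[idx < settings.n_channels]


def _resolve_start(phasor: PhasorSettings, decay: np.ndarray) -> int:
    if phasor.window_start == "peak":
        return int(np.argmax(decay))
    start = int(phasor.window_start)
    if not (0 <= start < len(decay)):
        raise InvalidInputError(f"window_start {start} outside channel range")
    return start


# ---------------------------------------------------------------------------
# the transform
# ---------------------------------------------------------------------------

def pixel_phasor(
    decay: Sequence[float] | np.ndarray,
    settings: AcquisitionSettings,
    phasor_settings: PhasorSettings | None = None,
    *,
    window_start: int | None = None,
) -> tuple[float, float]:
    """Phasor coordinates of a single decay histogram.

    Times are taken at channel centres measured from the window start; the
    transform frequency is ``omega = 2 pi k / T``.  With baseline subtraction
    on, the pre-rise minimum is removed first (clipped at zero).

    ``window_start`` overrides the settings' start policy — used by
    :func:`transform_cube` to impose the pooled-intensity peak on every pixel.
    """
    phasor_settings = phasor_settings or PhasorSettings()
    decay = np.asarray(decay, dtype=float)
    if decay.ndim != 1 or len(decay) != settings.n_channels:
        raise InvalidInputError(
            f"decay must be a 1D histogram of length {settings.n_channels}"
        )
    if (decay < 0).any():
        raise InvalidInputError("negative counts are not a valid histogram")
    if phasor_settings.baseline_subtraction:
        decay = np.clip(decay - _pre_rise_offset(decay), 0.0, None)
    if window_start is None:
        window_start = _resolve_start(phasor_settings, decay)
    idx = _window_indices(settings, phasor_settings, window_start)
    window = decay[idx]
    total = window.sum()
    if total <= 0:
        raise EmptyPixelError("zero total intensity in the summation window")
    t = (np.arange(len(idx)) + 0.5) * settings.channel_width
    wt = settings.omega(phasor_settings.harmonic) * t
    g = float((window * np.cos(wt)).sum() / total)
    s = float((window * np.sin(wt)).sum() / total)
    return g, s


def transform_cube(
    cube: DecayCube, phasor_settings: PhasorSettings | None = None
) -> PhasorCloud:
    """Transform every above-threshold pixel of a cube into the G-S plane.

    The intensity threshold is ``threshold_fraction`` of the brightest
    pixel's total photon count.  Pixels whose summation window is empty are
    excluded silently; an entirely empty result raises
    :class:`~flimphasor.errors.EmptyCloudError`.
    """
    phasor_settings = phasor_settings or PhasorSettings()
    settings = cube.settings
    totals = cube.intensity_image
    cutoff = phasor_settings.threshold_fraction * totals.max()
    mask = totals >= cutoff if cutoff > 0 else totals > 0
    if not mask.any():
        raise EmptyCloudError(
            f"no pixel reaches the threshold of {cutoff:.1f} photons "
            f"({phasor_settings.threshold_fraction:.0%} of the brightest pixel)"
        )
    rows, cols = np.nonzero(mask)
    decays = cube.counts[rows, cols, :].astype(float)  # (n, channels)

    if phasor_settings.baseline_subtraction:
        pooled_peak = int(np.argmax(decays.sum(axis=0)))
        if pooled_peak == 0:
            offsets = decays.min(axis=1)
        else:
            offsets = decays[:, :pooled_peak].min(axis=1)
        decays = np.clip(decays - offsets[:, None], 0.0, None)

    if phasor_settings.window_start == "peak":
        start = int(np.argmax(decays.sum(axis=0)))
    else:
        start = _resolve_start(phasor_settings, decays.sum(axis=0))
    idx = _window_indices(settings, phasor_settings, start)
    window = decays[:, idx]
    win_total = window.sum(axis=1)
    keep = win_total > 0
    if not keep.any():
        raise EmptyCloudError("all thresholded pixels are empty in the window")

    t = (np.arange(len(idx)) + 0.5) * settings.channel_width
    wt = settings.omega(phasor_settings.harmonic) * t
    g = (window[keep] @ np.cos(wt)) / win_total[keep]
    s = (window[keep] @ np.sin(wt)) / win_total[keep]
    return PhasorCloud(
        g=g,
        s=s,
        intensity=totals[rows, cols][keep].astype(float),
        pixels=np.column_stack([rows[keep], cols[keep]]),
        omega=settings.omega(phasor_settings.harmonic),
        source_settings=phasor_settings,
    )


# ---------------------------------------------------------------------------
# analytic phasor formulas
# ---------------------------------------------------------------------------

def mono_exponential_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Closed-form phasor of a mono-exponential decay.

    ``g = 1 / (1 + (wt)**2)``, ``s = wt / (1 + (wt)**2)`` with ``wt = omega *
    tau``; the point lies exactly on the universal circle for every tau >= 0
    (tau = 0 gives (1, 0); tau -> inf approaches (0, 0)).
    """
    if tau < 0:
        raise InvalidInputError("lifetime must be non-negative")
    if omega <= 0:
        raise InvalidInputError("omega must be positive")
    wt = omega * tau
    denom = 1.0 + wt * wt
    return 1.0 / denom, wt / denom


def mono_exponential_phasor_sampled(
    tau: float, omega: float, channel_width: float
) -> tuple[float, float]:
    """Exact phasor of a *channel-sampled* mono-exponential with periodic wrap.

    Channel-integrated counts of a periodically wrapped exponential form a
    geometric series; summed against ``exp(i w t)`` at channel centres over an
    integer number of transform cycles this gives

        P = exp(i w D / 2) * (1 - r) / (1 - r exp(i w D))

    with ``r = exp(-D / tau)`` and channel width ``D``.  As ``D -> 0`` this
    reduces to the continuous closed form.  It quantifies the (small)
    discretisation bias of the 64-channel transform, and serves as the
    analytic wrap correction for simulations.
    """
    if tau < 0:
        raise InvalidInputError("lifetime must be non-negative")
    if omega <= 0 or channel_width <= 0:
        raise InvalidInputError("omega and channel width must be positive")
    if tau == 0:
        phase = cmath.exp(1j * omega * channel_width / 2)
        return phase.real, phase.imag
    r = math.exp(-channel_width / tau)
    z = (
        cmath.exp(1j * omega * channel_width / 2)
        * (1.0 - r)
        / (1.0 - r * cmath.exp(1j * omega * channel_width))
    )
    return z.real, z.imag


def lifetime_from_point(point: tuple[float, float], omega: float) -> float:
    """Lifetime of a phasor point, ``tau = s / (g * omega)``.

    Exact inverse of :func:`mono_exponential_phasor` on the universal circle.
    Points with ``g <= 0`` correspond to lifetimes beyond the measurable
    range and are reported as ``math.inf`` rather than a finite number.
    """
    g, s = point
    if omega <= 0:
        raise InvalidInputError("omega must be positive")
    if g <= 0:
        return math.inf
    return s / (g * omega)


def calibrate_cloud(
    cloud: PhasorCloud, reference: PhasorCloud, reference_tau: float
) -> PhasorCloud:
    """Rotate/scale a cloud so a reference of known lifetime lands on-circle.

    The complex factor mapping the reference cloud's mean phasor onto
    ``mono_exponential_phasor(reference_tau, omega)`` is applied to every
    point.  This removes the instrument-response phase and modulation common
    to both measurements (IRF convolution multiplies all phasors by the same
    complex number), so calibrating a reference against itself puts its mean
    exactly on the universal circle.  The reference mean is intensity
    weighted — the phasor of the pooled reference decay — which is free of
    the per-pixel ratio bias of low-count pixels.
    """
    if not math.isclose(cloud.omega, reference.omega, rel_tol=1e-9):
        raise CalibrationError(
            "reference must be measured at the same transform frequency"
        )
    gm, sm = reference.mean_phasor(weighted=True)
    ref_mean = complex(gm, sm)
    if abs(ref_mean) < 1e-12:
        raise CalibrationError("reference mean phasor is at the origin")
    gt, st = mono_exponential_phasor(reference_tau, cloud.omega)
    factor = complex(gt, st) / ref_mean
    z = (cloud.g + 1j * cloud.s) * factor
    return replace(cloud, g=z.real, s=z.imag)


def calibrated_transform(
    cube: DecayCube,
    reference: DecayCube,
    reference_tau: float,
    phasor_settings: PhasorSettings | None = None,
) -> PhasorCloud:
    """Transform a cube and calibrate it against a reference measurement.

    The reference must be processed with the *identical* window, so when the
    start policy is ``"peak"`` the measurement cube's pooled-intensity peak
    channel is resolved once and imposed on both transforms; otherwise a
    one-channel difference in the two peaks would leave an uncorrected
    relative phase of ``omega * channel_width`` per channel of mismatch.
    """
    phasor_settings = phasor_settings or PhasorSettings()
    if phasor_settings.window_start == "peak":
        start = int(np.argmax(cube.pooled_decay()))
        phasor_settings = replace(phasor_settings, window_start=start)
    cloud = transform_cube(cube, phasor_settings)
    ref_cloud = transform_cube(reference, phasor_settings)
    return calibrate_cloud(cloud, ref_cloud, reference_tau)
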