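"""Geometry of the phasor (G-S) plane.

For a two-component decay every pixel's phasor lies on the chord between the
two mono-exponential component points on the universal circle, so a line
fitted through the cloud and intersected with the circle recovers the two
contributing lifetimes, and the position of the mean phasor along the chord
(lever rule) recovers the short component's fractional intensity.  The fit is
total least squares — orthogonal regression — because shot noise perturbs G
and S alike.  A 95% confidence ellipse over the cloud summarises its shape:
an axis ratio a/b near 1 marks a compact, mono-exponential-like cluster,
elongation marks multi-exponential spread.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    AmbiguousDirectionError,
    AnalysisStageError,
    DegenerateCloudError,
    DegenerateEllipseError,
    EmptyCloudError,
    NoIntersectionError,
    TangentLineError,
)
from .model import PhasorCloud, lifetime_from_point

__all__ = [
    "FittedLine",
    "LifetimePair",
    "ContributionResult",
    "ConfidenceEllipse",
    "PhasorFitResult",
    "tls_fit",
    "circle_intersections",
    "contributions",
    "confidence_ellipse",
    "analyze_cloud",
]

_CIRCLE_CENTER = np.array([0.5, 0.0])
_CIRCLE_RADIUS = 0.5


@dataclass(frozen=True)
class FittedLine:
    """A line ``centroid + t * direction`` in the G-S plane.

    The direction is unit length and sign-normalised: its g-component is
    >= 0, ties broken by s-component >= 0.
    """

    centroid: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if not math.isclose(norm, 1.0, abs_tol=1e-9):
            d = d / norm
        if d[0] < 0 or (d[0] == 0 and d[1] < 0):
            d = -d
        object.__setattr__(self, "direction", (float(d[0]), float(d[1])))
        c = np.asarray(self.centroid, dtype=float)
        object.__setattr__(self, "centroid", (float(c[0]), float(c[1])))


@dataclass(frozen=True)
class LifetimePair:
    """The two chord/circle intersections and their lifetimes (tau1 < tau2)."""

    tau1: float
    tau2: float
    p1: tuple[float, float]  # larger-g intersection, short lifetime
    p2: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.tau1 < self.tau2:
            raise ValueError("tau1 must be strictly smaller than tau2")


@dataclass(frozen=True)
class ContributionResult:
    """Lever-rule contribution of the short-lifetime component.

    ``alpha1`` grows from 0 at the long-lifetime intersection p2 to 1 at the
    short-lifetime intersection p1; ``beta1``/``beta2`` are the distances of
    the projected mean from p1 and p2.  ``boundary`` flags a projection that
    fell outside the chord (alpha was clipped).
    """

    alpha1: float
    beta1: float
    beta2: float
    projected_mean: tuple[float, float]
    boundary: bool = False


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Coverage ellipse of the cloud from its sample covariance."""

    center: tuple[float, float]
    a: float  # semi-major
    b: float  # semi-minor
    orientation: float  # radians, direction of the major axis
    coverage: float = 0.95

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")

    @property
    def ratio(self) -> float:
        return self.a / self.b


def tls_fit(cloud: PhasorCloud) -> FittedLine:
    """Total-least-squares line through a phasor cloud.

    The line passes through the unweighted centroid along the principal
    eigenvector of the centred covariance — the exact minimiser of summed
    squared *orthogonal* distances, accounting for errors in both G and S.
    """
    pts = np.column_stack([cloud.g, cloud.s])
    if len(pts) < 2 or np.allclose(pts, pts[0], atol=1e-15):
        raise DegenerateCloudError("need at least 2 distinct points for a line")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[1] <= 0:
        raise DegenerateCloudError("all points coincide; no principal direction")
    if eigvals[1] - eigvals[0] < 1e-12:
        raise AmbiguousDirectionError(
            f"principal spreads equal within 1e-12 "
            f"(eigenvalues {eigvals[0]:.3e}, {eigvals[1]:.3e}); "
            "the cloud is isotropic"
        )
    direction = eigvecs[:, 1]
    return FittedLine(centroid=tuple(centroid), direction=tuple(direction))


def circle_intersections(line: FittedLine, omega: float) -> LifetimePair:
    """Intersect a fitted line with the universal circle and read off lifetimes.

    Solves the line-circle quadratic, keeps the two intersections in the
    physical half-plane ``s >= 0``, labels the larger-g one p1 (short
    lifetime) and converts via ``tau = s / (g * omega)``.  tau1 < tau2 is
    guaranteed because lifetime increases counter-clockwise along the
    semicircle.  An intersection with g <= 0 is reported as an unbounded
    (infinite) lifetime.
    """
    c = np.asarray(line.centroid) - _CIRCLE_CENTER
    d = np.asarray(line.direction)
    # |c + t d|^2 = R^2  ->  t^2 + 2 (c.d) t + |c|^2 - R^2 = 0
    b_half = float(c @ d)
    const = float(c @ c) - _CIRCLE_RADIUS**2
    disc = b_half * b_half - const
    if disc < 0:
        raise NoIntersectionError(
            f"line misses the universal circle (discriminant {disc:.3e})"
        )
    if disc < 1e-12:
        raise TangentLineError("line is tangent to the universal circle")
    root = math.sqrt(disc)
    points = [
        np.asarray(line.centroid) + (-b_half + sign * root) * d
        for sign in (-1.0, 1.0)
    ]
    valid = [p for p in points if p[1] >= -1e-12]
    if len(valid) < 2:
        raise TangentLineError(
            "only one intersection lies in the physical half-plane s >= 0"
        )
    p1, p2 = sorted(valid, key=lambda p: -p[0])  # p1 has the larger g
    tau1 = lifetime_from_point((p1[0], p1[1]), omega)
    tau2 = lifetime_from_point((p2[0], p2[1]), omega)
    return LifetimePair(tau1=tau1, tau2=tau2, p1=tuple(p1), p2=tuple(p2))


def contributions(
    cloud: PhasorCloud, pair: LifetimePair, orientation: str = "lever"
) -> ContributionResult:
    """Lever-rule contribution of the short-lifetime component.

    The unweighted mean phasor is orthogonally projected onto the chord
    p1-p2; ``alpha1 = |proj - p2| / |p1 - p2|``, clipped to [0, 1] with a
    boundary flag when the projection falls outside the chord.  By phasor
    linearity this equals the short component's fractional intensity for a
    noiseless two-component mixture.

    ``orientation="literal"`` instead returns ``beta1 / (beta1 + beta2)``
    with beta1 the distance *from p1* — a convention under which alpha1
    falls as the cloud approaches the short-lifetime point.  It is exposed
    for comparison only; the lever convention matches the physical direction
    of metabolic shifts and the cross-check against amplitude fits.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot project an empty cloud")
    if orientation not in ("lever", "literal"):
        raise ValueError("orientation must be 'lever' or 'literal'")
    mean = np.asarray(cloud.mean_phasor())
    p1 = np.asarray(pair.p1)
    p2 = np.asarray(pair.p2)
    chord = p1 - p2
    length2 = float(chord @ chord)
    t = float((mean - p2) @ chord) / length2
    proj = p2 + t * chord
    beta1 = float(np.linalg.norm(proj - p1))
    beta2 = float(np.linalg.norm(proj - p2))
    boundary = not (0.0 <= t <= 1.0)
    if orientation == "lever":
        alpha1 = min(max(t, 0.0), 1.0)
    else:
        alpha1 = beta1 / (beta1 + beta2)
    return ContributionResult(
        alpha1=alpha1,
        beta1=beta1,
        beta2=beta2,
        projected_mean=(float(proj[0]), float(proj[1])),
        boundary=boundary,
    )


def confidence_ellipse(
    cloud: PhasorCloud, coverage: float = 0.95
) -> ConfidenceEllipse:
    """Coverage ellipse from the eigen-decomposition of the sample covariance.

    Semi-axes are ``sqrt(eigenvalue * q)`` with ``q`` the chi-square quantile
    at the coverage level for 2 degrees of freedom (5.991 at 95%), the
    standard bivariate-normal coverage region.
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    pts = np.column_stack([cloud.g, cloud.s])
    if len(pts) < 3:
        raise DegenerateEllipseError("need at least 3 points for an ellipse")
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-18:
        raise DegenerateEllipseError(
            f"cloud is collinear or coincident (smallest eigenvalue "
            f"{eigvals[0]:.3e})",
            eigenvalue=float(eigvals[0]),
        )
    q = stats.chi2.ppf(coverage, df=2)
    a = math.sqrt(eigvals[1] * q)
    b = math.sqrt(eigvals[0] * q)
    major = eigvecs[:, 1]
    return ConfidenceEllipse(
        center=tuple(pts.mean(axis=0)),
        a=a,
        b=b,
        orientation=float(math.atan2(major[1], major[0])),
        coverage=coverage,
    )


@dataclass(frozen=True)
class PhasorFitResult:
    """Bundle of the per-image phasor analysis.

    For multi-exponential clouds ``line``, ``pair`` and ``contribution`` are
    populated; for clouds flagged as effectively mono-exponential
    (``is_mono``) the single lifetime of the mean phasor is reported in
    ``tau_single`` instead.
    """

    n_points: int
    omega: float
    ellipse: ConfidenceEllipse
    line: FittedLine | None = None
    pair: LifetimePair | None = None
    contribution: ContributionResult | None = None
    tau_single: float | None = None
    is_mono: bool = False

    #: schema version of the serialised forms
    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": self.SCHEMA_VERSION,
            "n_pixels": self.n_points,
            "omega_rad_per_ps": self.omega,
            "is_mono": self.is_mono,
            "a": self.ellipse.a,
            "b": self.ellipse.b,
            "ratio": self.ellipse.ratio,
            "ellipse_center_g": self.ellipse.center[0],
            "ellipse_center_s": self.ellipse.center[1],
        }
        if self.is_mono:
            d["tau_ps"] = self.tau_single
        else:
            assert self.pair is not None and self.contribution is not None
            d["tau1_ps"] = self.pair.tau1
            d["tau2_ps"] = self.pair.tau2
            d["alpha1_phasor"] = self.contribution.alpha1
            d["beta1"] = self.contribution.beta1
            d["beta2"] = self.contribution.beta2
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_csv_row(self) -> tuple[str, str]:
        """(header, row) with the flat per-image summary fields."""
        fields = ["tau1_ps", "tau2_ps", "alpha1_phasor", "a", "b", "ratio",
                  "n_pixels"]
        d = self.to_dict()
        if self.is_mono:
            d.setdefault("tau1_ps", d.get("tau_ps"))
            d.setdefault("tau2_ps", "")
            d.setdefault("alpha1_phasor", "")
        row = ",".join(str(d.get(f, "")) for f in fields)
        return ",".join(fields), row


def analyze_cloud(
    cloud: PhasorCloud,
    *,
    coverage: float = 0.95,
    mono_ratio_threshold: float = 1.2,
    orientation: str = "lever",
) -> PhasorFitResult:
    """Full per-image phasor analysis: TLS line, intersections, lever, ellipse.

    Clouds whose TLS direction is ambiguous or whose ellipse axis ratio falls
    below ``mono_ratio_threshold`` are treated as effectively
    mono-exponential: the single lifetime of the mean phasor is reported and
    no line is intersected (a near-round cluster does not constrain a chord).
    Component failures are re-raised with the pipeline stage identified.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot analyse an empty cloud")

    try:
        ellipse = confidence_ellipse(cloud, coverage=coverage)
    except DegenerateEllipseError as exc:
        raise AnalysisStageError("confidence_ellipse", exc) from exc

    def _mono() -> PhasorFitResult:
        # a compact cluster acts as one uniform emitter: the pooled
        # (intensity-weighted) mean is the ratio-bias-free readout
        tau = lifetime_from_point(cloud.mean_phasor(weighted=True),
                                  cloud.omega)
        return PhasorFitResult(
            n_points=len(cloud), omega=cloud.omega, ellipse=ellipse,
            tau_single=tau, is_mono=True,
        )

    if ellipse.ratio < mono_ratio_threshold:
        return _mono()
    try:
        line = tls_fit(cloud)
    except AmbiguousDirectionError:
        return _mono()
    except DegenerateCloudError as exc:
        raise AnalysisStageError("tls_fit", exc) from exc
    try:
        pair = circle_intersections(line, cloud.omega)
    except (NoIntersectionError, TangentLineError) as exc:
        raise AnalysisStageError("circle_intersections", exc) from exc
    try:
        contribution = contributions(cloud, pair, orientation=orientation)
    except EmptyCloudError as exc:  # pragma: no cover - guarded above
        raise AnalysisStageError("contributions", exc) from exc
    return PhasorFitResult(
        n_points=len(cloud), omega=cloud.omega, ellipse=ellipse,
        line=line, pair=pair, contribution=contribution,
    )
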