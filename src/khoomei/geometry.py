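"""Vocal-tract geometry: midsagittal profiles, centerlines and area functions.

The tract is described at three levels:

* :class:`SagittalProfile` — the manually traced inner and outer contours of
  the airway in the midsagittal plane, ordered from glottis to lips (cm).
* :class:`CrossSectionSeries` — the centerline running between the two
  contours, with the cross-distance ``D(x)`` (perpendicular inner-to-outer
  distance) sampled along arc length ``x`` from the glottis.
* :class:`AreaFunction` — the 1-D area function ``A(x)`` obtained from the
  cross-distance under a circular-section assumption ``A = k D^alpha``
  (``k = pi/4``, ``alpha = 2``), the input to the acoustic model.

The centerline is found by iterative bisection: starting from the midpoint
of the glottal end, the algorithm marches in fixed arc steps, correcting each
new point along the local normal until it is equidistant from both contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import LineString, Point

__all__ = [
    "SagittalProfile",
    "CrossSectionSeries",
    "AreaFunction",
    "GeometryError",
    "ClosedTractError",
    "extract_centerline",
    "cross_distance_to_area",
    "resample_area_function",
    "read_profile_csv",
    "write_profile_csv",
    "read_area_csv",
    "write_area_csv",
]

#: circular cross-section scale factor, A = (pi/4) D^2
K_CIRCULAR = np.pi / 4.0
ALPHA_CIRCULAR = 2.0

#: arc-length extent at each end flagged low-confidence (perpendiculars
#: are ill-defined where the contours terminate)
END_MARGIN_CM = 0.5


class GeometryError(ValueError):
    """Raised when a profile violates geometric preconditions."""


class ClosedTractError(ValueError):
    """Raised when a cross-distance or area is non-positive."""


@dataclass
class SagittalProfile:
    """Traced inner and outer airway contours, glottis first, in cm."""

    inner: np.ndarray  # (N, 2)
    outer: np.ndarray  # (M, 2)

    def __post_init__(self) -> None:
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        for name, c in (("inner", self.inner), ("outer", self.outer)):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise GeometryError(f"{name} contour needs >= 3 2-D points")
            if not np.all(np.isfinite(c)):
                raise GeometryError(f"{name} contour has non-finite points")
        if LineString(self.inner).intersects(LineString(self.outer)):
            raise GeometryError("inner and outer contours intersect")


@dataclass
class CrossSectionSeries:
    """Centerline with arc length ``x`` and cross-distance ``D`` (cm)."""

    centerline: np.ndarray  # (N, 2)
    x: np.ndarray  # (N,) cm from glottis, x[0] = 0
    D: np.ndarray  # (N,) cm, > 0
    low_confidence: np.ndarray = field(default=None)  # bool mask near ends

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if not (len(self.x) == len(self.D) == len(self.centerline)):
            raise ValueError("centerline, x and D must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.D <= 0):
            raise ClosedTractError("cross-distance must be positive")
        if self.low_confidence is None:
            self.low_confidence = (self.x < self.x[0] + END_MARGIN_CM) | (
                self.x > self.x[-1] - END_MARGIN_CM
            )


@dataclass
class AreaFunction:
    """1-D area function: section positions ``x`` (cm) and areas ``A`` (cm^2)."""

    x: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if len(self.x) != len(self.A):
            raise ValueError("x and A must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.A <= 0):
            raise ClosedTractError("areas must be positive")

    @property
    def L(self) -> float:
        """Total tract length (cm)."""
        return float(self.x[-1])

    @property
    def n_sections(self) -> int:
        return len(self.x)

    def is_uniform_grid(self, rtol: float = 1e-6) -> bool:
        dx = np.diff(self.x)
        return bool(np.allclose(dx, dx[0], rtol=rtol))

    def copy(self) -> "AreaFunction":
        return AreaFunction(self.x.copy(), self.A.copy())


def _signed_side(point: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    d = point - origin
    return direction[0] * d[1] - direction[1] * d[0]


def extract_centerline(
    profile: SagittalProfile,
    arc_step: float = 0.25,
    max_points: int = 2000,
) -> CrossSectionSeries:
    """Find the centerline between the two contours by iterative bisection.

    Starting from the midpoint of the glottal end segment (the first points
    of both contours), march in ``arc_step`` increments; at each step the new
    point is slid along the normal of the previous centerline segment until
    its distances to the inner and outer polylines are equal.  The
    cross-distance at each centerline point is the sum of the two polyline
    distances (the inner-to-outer distance along the local perpendicular).

    Points within 0.5 cm of either end are flagged low-confidence.
    """
    inner = LineString(profile.inner)
    outer = LineString(profile.outer)

    def imbalance(p: np.ndarray) -> float:
        return inner.distance(Point(p)) - outer.distance(Point(p))

    start = 0.5 * (profile.inner[0] + profile.outer[0])
    end = 0.5 * (profile.inner[-1] + profile.outer[-1])

    pts = [start]
    direction = end - start
    direction = direction / np.linalg.norm(direction)

    for _ in range(max_points):
        prev = pts[-1]
        if np.linalg.norm(end - prev) <= arc_step:
            break
        cand = prev + arc_step * direction
        normal = np.array([-direction[1], direction[0]])

        # bracket the equidistant point along the normal
        half_span = max(inner.distance(Point(cand)), outer.distance(Point(cand)), arc_step)
        lo, hi = -half_span, half_span
        f_lo = imbalance(cand + lo * normal)
        f_hi = imbalance(cand + hi * normal)
        grow = 0
        while f_lo * f_hi > 0 and grow < 6:
            lo *= 1.6
            hi *= 1.6
            f_lo = imbalance(cand + lo * normal)
            f_hi = imbalance(cand + hi * normal)
            grow += 1
        if f_lo * f_hi > 0:
            warnings.warn("centerline bisection lost the equidistant locus; trimming")
            break
        t = brentq(lambda s: imbalance(cand + s * normal), lo, hi, xtol=1e-6)
        new = cand + t * normal
        pts.append(new)
        step_vec = new - prev
        norm = np.linalg.norm(step_vec)
        if norm < 1e-12:
            break
        direction = step_vec / norm

    pts.append(end)
    centerline = np.asarray(pts)
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    x = np.concatenate([[0.0], np.cumsum(seg)])
    D = np.array([inner.distance(Point(p)) + outer.distance(Point(p)) for p in centerline])

    keep = D > 1e-9
    if not np.all(keep):
        warnings.warn("degenerate cross-distances near the ends were trimmed")
        centerline, x, D = centerline[keep], x[keep], D[keep]
        x = x - x[0]
    return CrossSectionSeries(centerline=centerline, x=x, D=D)


def cross_distance_to_area(
    series: CrossSectionSeries,
    k: float = K_CIRCULAR,
    alpha: float = ALPHA_CIRCULAR,
) -> AreaFunction:
    """Convert cross-distances to areas via ``A(x) = k * D(x)**alpha``.

    With the circular-section assumption (elements of D are diameters),
    ``k = pi/4`` and ``alpha = 2``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if np.any(series.D <= 0):
        raise ClosedTractError("cross-distance contains non-positive values")
    return AreaFunction(x=series.x.copy(), A=k * series.D**alpha)


def resample_area_function(af: AreaFunction, n_sections: int) -> AreaFunction:
    """Resample onto ``n_sections`` equal-length sections covering [0, L].

    Areas are interpolated piecewise-linearly in ``A`` vs ``x``; the endpoint
    areas are preserved exactly.
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    x_new = np.linspace(af.x[0], af.x[-1], n_sections)
    A_new = np.interp(x_new, af.x, af.A)
    return AreaFunction(x=x_new, A=A_new)


# ---------------------------------------------------------------------------
# CSV I/O


def write_profile_csv(profile: SagittalProfile, path) -> None:
    import pandas as pd

    rows = []
    for name, contour in (("inner", profile.inner), ("outer", profile.outer)):
        for i, (px, py) in enumerate(contour):
            rows.append({"contour": name, "index": i, "x_cm": px, "y_cm": py})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profile_csv(path) -> SagittalProfile:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"contour", "index", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile CSV needs columns {sorted(required)}")
    parts = {}
    for name, grp in df.groupby("contour"):
        grp = grp.sort_values("index")
        parts[name] = grp[["x_cm", "y_cm"]].to_numpy()
    return SagittalProfile(inner=parts["inner"], outer=parts["outer"])


def write_area_csv(af: AreaFunction, path) -> None:
    import pandas as pd

    pd.DataFrame({"x_cm": af.x, "A_cm2": af.A}).to_csv(path, index=False)


def read_area_csv(path) -> AreaFunction:
    import pandas as pd

    df = pd.read_csv(path)
    if "A_cm2" in df.columns:
        return AreaFunction(x=df["x_cm"].to_numpy(), A=df["A_cm2"].to_numpy())
    if "D_cm" in df.columns:
        series = df["D_cm"].to_numpy()
        return AreaFunction(x=df["x_cm"].to_numpy(), A=K_CIRCULAR * series**2)
    raise ValueError("area CSV needs x_cm plus A_cm2 or D_cm")
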