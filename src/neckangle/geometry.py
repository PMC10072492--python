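"""2D geometric primitives of the direct torsion construction.

The construction drawn by the investigators on the neck-aligned axial
section reduces to a handful of primitives: a least-squares circle fit
(femoral head, lateral head opening), a supporting tangent along the
ventral cortex of the greater trochanter, a parallel line at the dorsal
border, circles inscribed between the two lines (lateral neck), the
axes through circle-center pairs, and the signed intersection angle.

All coordinates are in millimetres in the section plane.  The ventral
(anterior) in-plane direction serves as the sign reference: a medial
axis rotated ventrally relative to the lateral axis is anteversion and
is reported positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def _as_unit(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(2)
    n = float(np.linalg.norm(a))
    if n < 1e-12:
        raise ValueError("zero-length direction")
    return a / n


def _perp(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counter-clockwise)."""
    return np.array([-v[1], v[0]])


def _cross(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


@dataclass(frozen=True)
class Circle2D:
    """A circle in section-plane coordinates (mm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        object.__setattr__(self, "radius", float(self.radius))
        if not self.radius > 0:
            raise ValueError("circle radius must be positive")


@dataclass(frozen=True)
class Line2D:
    """An (undirected) line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_point(self.point))
        object.__setattr__(self, "direction", _as_unit(self.direction))

    def signed_distance(self, p) -> float:
        """Signed offset of ``p`` from the line, positive toward
        ``perp(direction)``."""
        return float(np.dot(_as_point(p) - self.point, _perp(self.direction)))

    def project_coordinate(self, p) -> float:
        """Along-line coordinate of the foot of ``p``."""
        return float(np.dot(_as_point(p) - self.point, self.direction))

    def at(self, t: float) -> np.ndarray:
        return self.point + float(t) * self.direction


@dataclass(frozen=True)
class AxisPair:
    """The two neck axes of the construction.

    ``medial_axis`` joins the femoral-head circle center and the
    lateral-head-opening circle center; ``lateral_axis`` joins the two
    circles inscribed between the tangent and the parallel line.
    """

    medial_axis: Line2D
    lateral_axis: Line2D

    def __post_init__(self):
        c = abs(_cross(self.medial_axis.direction, self.lateral_axis.direction))
        d = self.medial_axis.signed_distance(self.lateral_axis.point)
        if c < 1e-12 and abs(d) < 1e-9:
            raise ValueError("medial and lateral axes are identical")


def fit_circle(points) -> Circle2D:
    """Least-squares circle through ``points``.

    Pratt's algebraic fit -- the circle equation
    ``a(x^2+y^2) + bx + cy + d = 0`` subject to ``b^2+c^2-4ad = 1``,
    stable for partial arcs such as the femoral head seen as an arc on
    an axial section -- seeds a short Gauss-Newton refinement of the
    geometric residual, so the result minimizes the sum of squared
    radial distances.  Exact for points on a circle.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 2)")
    centroid = pts.mean(axis=0)
    xy = pts - centroid
    # collinearity check via the smaller singular value of the spread
    sv = np.linalg.svd(xy, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("points are collinear; no circle fits")
    z = np.sum(xy ** 2, axis=1)
    B = np.column_stack([z, xy[:, 0], xy[:, 1], np.ones(len(xy))])
    M = B.T @ B / len(xy)
    # Pratt constraint matrix for b^2 + c^2 - 4ad = 1
    C = np.array([
        [0.0, 0.0, 0.0, -2.0],
        [0.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [-2.0, 0.0, 0.0, 0.0],
    ])
    vals, vecs = scipy.linalg.eig(M, C)
    vals = np.real(vals)
    finite = np.isfinite(vals)
    # the Pratt solution is the eigenvector of the smallest non-negative
    # generalized eigenvalue (0 for an exact fit)
    cand = np.where(finite & (vals > -1e-11))[0]
    if cand.size == 0:  # pragma: no cover - defensive
        raise ValueError("degenerate circle fit")
    k = cand[np.argmin(vals[cand])]
    a, b, c, d = np.real(vecs[:, k])
    if abs(a) < 1e-14:
        raise ValueError("points are collinear; no circle fits")
    cx, cy = -b / (2 * a), -c / (2 * a)
    r2 = (b * b + c * c - 4 * a * d) / (4 * a * a)
    if r2 <= 0:  # pragma: no cover - defensive
        raise ValueError("degenerate circle fit")

    def residuals(p):
        return np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) - p[2]

    sol = scipy.optimize.least_squares(residuals,
                                       x0=[cx, cy, float(np.sqrt(r2))],
                                       method="lm", xtol=1e-14, ftol=1e-14)
    cx, cy, r = sol.x
    if r <= 0:  # pragma: no cover - defensive
        raise ValueError("degenerate circle fit")
    return Circle2D(center=np.array([cx, cy]) + centroid, radius=float(r))


def supporting_tangent(contour, outward_direction) -> Line2D:
    """Supporting line of a contour, extremal in ``outward_direction``.

    Formalizes the hand-drawn tangent along a cortex: the line touches
    the contour's convex hull at its extremal point in the outward
    direction, every contour point lies on the non-outward side, and the
    line direction is perpendicular to ``outward_direction``.
    """
    pts = np.atleast_2d(np.asarray(contour, dtype=float))
    if pts.size == 0:
        raise ValueError("empty contour")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must have shape (n, 2)")
    n = _as_unit(outward_direction)
    proj = pts @ n
    p = pts[int(np.argmax(proj))]
    return Line2D(point=p, direction=_perp(n))


def parallel_through_point(line: Line2D, point) -> Line2D:
    """The line parallel to ``line`` through ``point``."""
    return Line2D(point=_as_point(point), direction=line.direction)


def inscribed_circle_between_lines(band_lower: Line2D, band_upper: Line2D,
                                   station, *, angle_tol_deg: float = 0.5) -> Circle2D:
    """Circle tangent to two parallel lines, nearest to ``station``.

    The circle's radius is half the inter-line distance, its center lies
    on the mid-line at the along-line coordinate of ``station``.
    ``station`` must lie strictly between the lines.
    """
    d1, d2 = band_lower.direction, band_upper.direction
    sin_ang = abs(_cross(d1, d2))
    if sin_ang > np.sin(np.radians(angle_tol_deg)):
        raise ValueError(
            f"band lines are not parallel (angle {np.degrees(np.arcsin(sin_ang)):.3f} deg)")
    st = _as_point(station)
    off_upper = band_lower.signed_distance(band_upper.point)
    if abs(off_upper) < 1e-12:
        raise ValueError("band lines coincide")
    off_station = band_lower.signed_distance(st)
    if not (0.0 < off_station / off_upper < 1.0):
        raise ValueError("station does not lie strictly between the band lines")
    nhat = _perp(band_lower.direction)
    mid_point = band_lower.point + 0.5 * off_upper * nhat
    midline = Line2D(point=mid_point, direction=band_lower.direction)
    t = midline.project_coordinate(st)
    return Circle2D(center=midline.at(t), radius=abs(off_upper) / 2.0)


def axis_from_centers(c1: Circle2D, c2: Circle2D) -> Line2D:
    """The connecting line between two circle centers."""
    delta = c2.center - c1.center
    if np.linalg.norm(delta) <= 1e-6:
        raise ValueError("circle centers coincide; axis undefined")
    return Line2D(point=c1.center, direction=delta)


def angle_between_axes(pair: AxisPair, sign_reference) -> float:
    """Signed acute angle (degrees) between the medial and lateral axes.

    Positive when the medial axis is rotated toward ``sign_reference``
    (the ventral direction) relative to the lateral axis, i.e.
    anteversion positive, retroversion negative.  Both axes are
    undirected; they are oriented 90 degrees clockwise from the sign
    reference (medially, for a ventral reference) before the signed
    angle is taken, which makes the convention side-independent.
    """
    s = _as_unit(sign_reference)
    canonical = np.array([s[1], -s[0]])  # 90 deg clockwise from reference
    l = pair.lateral_axis.direction
    m = pair.medial_axis.direction
    if np.dot(l, canonical) < 0:
        l = -l
    if np.dot(m, l) < 0:
        m = -m
    ang = np.degrees(np.arctan2(_cross(l, m), float(np.dot(l, m))))
    if ang > 90.0:
        ang -= 180.0
    sgn = 1.0 if _cross(l, s) >= 0 else -1.0
    return float(sgn * ang)
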