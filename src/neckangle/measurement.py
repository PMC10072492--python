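"""The direct CT torsion measurement pipeline.

Stages, mirroring the manual procedure on the workstation:

1. ``align_neck_frame`` -- refine the operator-supplied head-center and
   neck-direction hints and erect the neck-aligned section frame.  The
   section is near-axial: its normal is the superior axis tilted a few
   degrees laterally in the frontal view (the section is "guided down
   near the Adam's bow"), its in-plane x axis is the axial projection
   of the neck axis, and its origin sits at the calcar level.
2. ``extract_axial_slab`` -- resample a 5-mm slab around the section
   plane (mean-intensity projection).
3. ``extract_cortex_contours`` -- threshold, separate the two
   fragments across the osteotomy gap, and label the four landmark
   contours: femoral head arc, lateral head opening (medial neck stump
   cortices), ventral cortex of the greater trochanter, dorsal cortex
   at the lesser trochanter.
4. ``measure_torsion`` -- run the geometric construction (tangent,
   parallel line, head + opening circles, two inscribed neck circles,
   two axes) and report the signed intersection angle, anteversion
   positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .geometry import (AxisPair, Circle2D, Line2D, axis_from_centers,
                       angle_between_axes, fit_circle,
                       inscribed_circle_between_lines, parallel_through_point,
                       supporting_tangent)
from .util import project_out, unit
from .volume import Volume


class MeasurementError(RuntimeError):
    """Pipeline failure, tagged with the construction stage that failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class MeasurementHints:
    """Operator hints: approximate displaced-head center (world mm) and
    the lateral-fragment neck direction (head toward neck base)."""

    head_center: np.ndarray
    neck_direction: np.ndarray
    superior: np.ndarray = (0.0, 0.0, 1.0)
    anterior: np.ndarray = (0.0, -1.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "head_center",
                           np.asarray(self.head_center, float).reshape(3))
        object.__setattr__(self, "neck_direction", unit(self.neck_direction))
        object.__setattr__(self, "superior", unit(self.superior))
        object.__setattr__(self, "anterior", unit(self.anterior))

    @classmethod
    def from_phantom_meta(cls, meta: dict) -> "MeasurementHints":
        return cls(head_center=np.asarray(meta["head_center"], float),
                   neck_direction=np.asarray(meta["neck_axis_direction"], float))


@dataclass(frozen=True)
class MeasureParams:
    """Tunables of the pipeline (lengths mm, angles degrees)."""

    threshold: float = 150.0            # bone threshold between background and cortex
    smooth_sigma: float = 0.6           # in-plane Gaussian (mm) before contouring,
                                        # emulating the scanner PSF and taming
                                        # contour aliasing on near-grid edges
    slab_thickness: float = 5.0         # acquisition slab of the study protocol
    in_plane_spacing: float = None      # default: min volume spacing
    slab_extent: tuple = ((-80.0, 32.0), (-46.0, 46.0))
    calcar_offset: float = 10.0         # section level below head center ("Adam's bow")
    frontal_tilt_deg: float = 10.0      # lateral dip of the section in the frontal view
    head_radius: float = 24.0           # expected head radius for landmark windows
    head_annulus: float = 2.5           # tolerance band around the head disc
    stump_window: tuple = (23.0, 34.0)  # in-plane mm from head center: medial stump cortex
    facet_band: float = 1.0             # depth of the ventral-cortex band used for alignment
    min_facet_points: int = 6
    refine_iterations: int = 2
    min_side_points: int = 4
    neck_stations: tuple = (0.35, 0.65) # fractions along the band for the inscribed circles
    anteversion_positive: bool = True
    refine_direction: bool = True


@dataclass(frozen=True)
class SectionFrame:
    """Oriented reformat frame centered on the femoral neck.

    ``axes`` rows are (e1, e2, e3): e1 = in-plane medialward neck axis,
    e2 = in-plane ventral, e3 = their cross product (slab normal up to
    sign).  Right-handed and orthonormal by construction.
    """

    origin: np.ndarray
    axes: np.ndarray
    head_center: np.ndarray = None
    neck_direction: np.ndarray = None

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        A = np.asarray(self.axes, float).reshape(3, 3)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame must be right-handed")
        object.__setattr__(self, "axes", A)

    def to_plane(self, world) -> np.ndarray:
        """World point -> (x, y) in-plane slab coordinates (mm)."""
        d = np.asarray(world, float) - self.origin
        return np.array([d @ self.axes[0], d @ self.axes[1]])


@dataclass(frozen=True)
class Slice2D:
    """Resampled slab: values[y, x] on the section frame grid."""

    values: np.ndarray
    spacing: np.ndarray
    frame: SectionFrame
    slab_thickness: float
    origin2d: np.ndarray

    def __post_init__(self):
        if self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, float).reshape(2))
        object.__setattr__(self, "origin2d", np.asarray(self.origin2d, float).reshape(2))


@dataclass(frozen=True)
class ContourSet:
    """Labeled landmark contours in slab coordinates (mm)."""

    head_arc: np.ndarray
    stump_side_a: np.ndarray
    stump_side_b: np.ndarray
    gt_ventral: np.ndarray
    dorsal_lt: np.ndarray
    medial_points: np.ndarray
    lateral_points: np.ndarray
    head_center_2d: np.ndarray
    head_disc_radius: float


@dataclass(frozen=True)
class TorsionMeasurement:
    """Result of the direct measurement with its full construction."""

    angle_deg: float
    circles: tuple            # (head, lateral opening, neck 1, neck 2)
    tangent: Line2D
    parallel: Line2D
    axes: AxisPair
    slice_ref: dict
    contours: ContourSet = None

    def __post_init__(self):
        if abs(self.angle_deg) > 90.0:
            raise ValueError("torsion magnitude cannot exceed 90 degrees")

    @property
    def head_circle(self) -> Circle2D:
        return self.circles[0]

    @property
    def opening_circle(self) -> Circle2D:
        return self.circles[1]

    @property
    def neck_circles(self) -> tuple:
        return self.circles[2:]

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "circles": [{"center": c.center.tolist(), "radius": c.radius}
                        for c in self.circles],
            "tangent": {"point": self.tangent.point.tolist(),
                        "direction": self.tangent.direction.tolist()},
            "parallel": {"point": self.parallel.point.tolist(),
                         "direction": self.parallel.direction.tolist()},
            "medial_axis": {"point": self.axes.medial_axis.point.tolist(),
                            "direction": self.axes.medial_axis.direction.tolist()},
            "lateral_axis": {"point": self.axes.lateral_axis.point.tolist(),
                             "direction": self.axes.lateral_axis.direction.tolist()},
            "slice_ref": self.slice_ref,
        }


# ---------------------------------------------------------------------------
# stage 1: frame alignment


def _bone_positions_near(volume: Volume, center, half_size, threshold):
    """World positions of bone voxels within a world-axis-aligned crop
    box (mapped through the volume orientation via its corners)."""
    center = np.asarray(center, float)
    corners = center + half_size * (np.array(np.meshgrid([-1, 1], [-1, 1], [-1, 1]))
                                    .T.reshape(-1, 3))
    idx = volume.world_to_index(corners)
    lo_idx = np.clip(np.floor(idx.min(axis=0)).astype(int), 0,
                     np.array(volume.shape) - 1)
    hi_idx = np.clip(np.ceil(idx.max(axis=0)).astype(int), 0,
                     np.array(volume.shape) - 1)
    if np.any(hi_idx <= lo_idx):
        return np.empty((0, 3))
    sub = volume.values[lo_idx[0]:hi_idx[0] + 1,
                        lo_idx[1]:hi_idx[1] + 1,
                        lo_idx[2]:hi_idx[2] + 1]
    ii = np.argwhere(sub > threshold)
    if ii.size == 0:
        return np.empty((0, 3))
    return volume.index_to_world(ii + lo_idx)


def _refine_head_center(volume, hint, neck_direction, params):
    """Iterated centroid of bright voxels in a ball around the estimate.

    The ball clips the head surface (radius > head radius), so the
    centroid is pulled toward the true center; a symmetric band along
    the neck axis excludes the attached neck stump, which would
    otherwise drag the centroid laterally.
    """
    c = np.asarray(hint, float).copy()
    u = unit(neck_direction)
    r = 1.1 * params.head_radius
    band = 0.8 * params.head_radius
    for _ in range(6):
        pos = _bone_positions_near(volume, c, r + 2.0, params.threshold)
        if len(pos) == 0:
            raise MeasurementError("align_neck_frame",
                                   "no bone voxels near the head-center hint")
        rel = pos - c
        keep = (np.linalg.norm(rel, axis=1) <= r) & (np.abs(rel @ u) <= band)
        if not np.any(keep):
            raise MeasurementError("align_neck_frame",
                                   "no bone voxels near the head-center hint")
        c = pos[keep].mean(axis=0)
    return c


def _build_frame(hc, u, params, s, ant) -> SectionFrame:
    u_axial = unit(project_out(u, s))
    g = np.radians(params.frontal_tilt_deg)
    normal = unit(np.cos(g) * s + np.sin(g) * u_axial)
    e1 = unit(project_out(-u, normal))       # medialward, in-plane
    e2 = np.cross(normal, e1)
    if np.dot(e2, ant) < 0:
        e2 = -e2
    e3 = np.cross(e1, e2)
    origin = hc - params.calcar_offset * s
    return SectionFrame(origin=origin, axes=np.vstack([e1, e2, e3]),
                        head_center=hc, neck_direction=u)


def _ventral_facet_direction(volume, frame, params):
    """In-plane direction of the greater trochanter's flat ventral
    cortex, fitted on the lateral fragment's ventral-extreme contour
    band.  Returns the signed in-plane angle (deg) between the facet
    and the frame's neck axis."""
    from .geometry import Line2D  # local import keeps module order simple

    slab = extract_axial_slab(volume, frame, params.slab_thickness,
                              extent=params.slab_extent,
                              spacing=params.in_plane_spacing)
    cs = extract_cortex_contours(slab, params.threshold, params)
    pts = cs.gt_ventral
    band = pts[pts[:, 1] >= pts[:, 1].max() - params.facet_band]
    if len(band) < params.min_facet_points:
        raise MeasurementError("align_neck_frame",
                               "ventral trochanter cortex too short to align on")
    c = band.mean(axis=0)
    _, _, vt = np.linalg.svd(band - c)
    d = vt[0]
    if d[0] < 0:
        d = -d
    return float(np.degrees(np.arctan2(d[1], d[0])))


def align_neck_frame(volume: Volume, head_center_hint, neck_direction_hint,
                     params: MeasureParams = None,
                     superior=(0.0, 0.0, 1.0), anterior=(0.0, -1.0, 0.0)) -> SectionFrame:
    """Erect the neck-aligned near-axial section frame from hints.

    The head center is refined to the centroid of the bright head
    sphere.  The in-plane orientation is then refined by aligning the
    frame with the flat ventral cortex of the greater trochanter (the
    cortex the tangent is drawn along), which is parallel to the intact
    neck axis; this emulates the operator rotating the section until it
    runs along the neck, and makes the lateral reference direction an
    image-content measurement rather than a hint.
    """
    params = params or MeasureParams()
    hint = np.asarray(head_center_hint, float).reshape(3)
    idx = np.asarray(volume.world_to_index(hint))
    if np.any(idx < -0.5) or np.any(idx > np.array(volume.shape) - 0.5):
        raise MeasurementError("align_neck_frame", "head-center hint outside volume")
    s = unit(superior)
    ant = unit(anterior)
    u = unit(neck_direction_hint)  # lateralward, head -> neck base
    hc = _refine_head_center(volume, hint, u, params)
    frame = _build_frame(hc, u, params, s, ant)
    if params.refine_direction:
        from .util import rotation_matrix

        for _ in range(params.refine_iterations):
            delta = _ventral_facet_direction(volume, frame, params)
            u = rotation_matrix(frame.axes[2], delta) @ u
            frame = _build_frame(hc, u, params, s, ant)
    return frame


# ---------------------------------------------------------------------------
# stage 2: slab extraction


def extract_axial_slab(volume: Volume, frame: SectionFrame,
                       thickness: float = 5.0, *, extent=None,
                       spacing: float = None) -> Slice2D:
    """Mean-intensity projection of a slab around the section plane."""
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    extent = extent if extent is not None else MeasureParams().slab_extent
    sp = float(spacing) if spacing else float(np.min(volume.spacing))
    (x0, x1), (y0, y1) = extent
    xs = np.arange(x0, x1 + sp / 2, sp)
    ys = np.arange(y0, y1 + sp / 2, sp)
    if thickness <= sp:  # degenerate slab: a single reformatted plane
        n_planes = 1
        ws = np.array([0.0])
    else:
        n_planes = max(3, int(round(thickness / sp)) + 1)
        ws = np.linspace(-thickness / 2.0, thickness / 2.0, n_planes)
    e1, e2, e3 = frame.axes
    grid = (frame.origin[None, None, None, :]
            + xs[None, :, None, None] * e1
            + ys[:, None, None, None] * e2
            + ws[None, None, :, None] * e3)
    idx = volume.world_to_index(grid.reshape(-1, 3)).T
    inside = np.all((idx > -0.5) & (idx < (np.array(volume.shape)[:, None] - 0.5)),
                    axis=0)
    if not inside.any():
        raise MeasurementError("extract_axial_slab", "slab lies outside the volume")
    sampled = ndimage.map_coordinates(np.asarray(volume.values, float), idx,
                                      order=1, mode="constant", cval=0.0)
    values = sampled.reshape(len(ys), len(xs), n_planes).mean(axis=2)
    return Slice2D(values=values, spacing=(sp, sp), frame=frame,
                   slab_thickness=thickness, origin2d=(xs[0], ys[0]))


# ---------------------------------------------------------------------------
# stage 3: contour extraction and landmark labeling


def _labeled_contours_mm(vals, threshold, labels, slice2d):
    """Sub-pixel iso-contours of the (smoothed) slab at the bone
    threshold, each assigned to the connected component whose pixels it
    outlines."""
    mask = labels > 0
    _, (inds_r, inds_c) = ndimage.distance_transform_edt(~mask, return_indices=True)
    out = {}
    for c in skmeasure.find_contours(vals, threshold):
        rr = np.clip(np.round(c[:, 0]).astype(int), 0, labels.shape[0] - 1)
        cc = np.clip(np.round(c[:, 1]).astype(int), 0, labels.shape[1] - 1)
        lab = labels[inds_r[rr, cc], inds_c[rr, cc]]
        lab = int(np.bincount(lab[lab > 0]).argmax()) if np.any(lab > 0) else 0
        if lab == 0:
            continue
        xy = np.column_stack([slice2d.origin2d[0] + c[:, 1] * slice2d.spacing[0],
                              slice2d.origin2d[1] + c[:, 0] * slice2d.spacing[1]])
        out.setdefault(lab, []).append(xy)
    return {k: np.vstack(v) for k, v in out.items()}


def extract_cortex_contours(slice2d: Slice2D, threshold: float,
                            params: MeasureParams = None) -> ContourSet:
    """Threshold the slab, split medial/lateral fragments, label landmarks."""
    params = params or MeasureParams()
    vals = slice2d.values
    if params.smooth_sigma > 0:
        vals = ndimage.gaussian_filter(vals, params.smooth_sigma
                                       / np.asarray(slice2d.spacing))
    mask = vals > threshold
    if not mask.any():
        raise MeasurementError("extract_cortex_contours",
                               "no cortex found above threshold")
    labels = skmeasure.label(mask, connectivity=2)
    h2 = slice2d.frame.to_plane(slice2d.frame.head_center)
    yy, xx = np.nonzero(mask)
    px = np.column_stack([slice2d.origin2d[0] + xx * slice2d.spacing[0],
                          slice2d.origin2d[1] + yy * slice2d.spacing[1]])
    nearest = np.argmin(np.linalg.norm(px - h2, axis=1))
    medial_label = labels[yy[nearest], xx[nearest]]
    other = np.bincount(labels[(labels > 0) & (labels != medial_label)].ravel())
    if other.size == 0 or other.max() == 0:
        raise MeasurementError("extract_cortex_contours",
                               "lateral fragment not found (osteotomy gap "
                               "not resolved in the section)")
    lateral_label = int(np.argmax(other))

    by_label = _labeled_contours_mm(vals, threshold, labels, slice2d)
    med_pts = by_label.get(int(medial_label), np.empty((0, 2)))
    lat_pts = by_label.get(int(lateral_label), np.empty((0, 2)))
    if len(med_pts) == 0 or len(lat_pts) == 0:
        raise MeasurementError("extract_cortex_contours", "fragment contour empty")

    dz = abs(float((slice2d.frame.head_center - slice2d.frame.origin)
                   @ slice2d.frame.axes[2]))
    r_disc = float(np.sqrt(max(params.head_radius ** 2 - dz ** 2,
                               (0.3 * params.head_radius) ** 2)))

    # iterative re-centering: fit the head circle, re-select the arc
    # annulus around the fit; makes the arc (and everything anchored on
    # it) insensitive to hint errors
    h2_est, r_est = h2, r_disc
    head_arc = None
    for _ in range(3):
        dist = np.linalg.norm(med_pts - h2_est, axis=1)
        head_arc = med_pts[np.abs(dist - r_est) <= params.head_annulus]
        if len(head_arc) < 8:
            raise MeasurementError("extract_cortex_contours",
                                   "femoral head arc not found")
        circ = fit_circle(head_arc)
        h2_est = circ.center
        r_est = float(np.clip(circ.radius, 0.6 * r_disc, 1.4 * r_disc))
    # final tight pass: keep only points hugging the converged circle,
    # dropping junction/stump contamination at the annulus fringe
    tight = max(0.6, 0.75 * float(np.min(slice2d.spacing)))
    dist = np.linalg.norm(med_pts - h2_est, axis=1)
    arc = med_pts[np.abs(dist - r_est) <= tight]
    if len(arc) >= 8:
        head_arc = arc
        circ = fit_circle(head_arc)
        h2_est = circ.center
        r_est = float(np.clip(circ.radius, 0.6 * r_disc, 1.4 * r_disc))
    h2 = h2_est

    dist = np.linalg.norm(med_pts - h2, axis=1)
    stump = med_pts[dist > r_est + 0.8 * params.head_annulus]
    if len(stump) < 2 * params.min_side_points:
        raise MeasurementError("extract_cortex_contours",
                               "lateral head opening region not found")
    d0 = unit(stump.mean(axis=0) - h2)
    rel = stump - h2
    proj = rel @ d0
    w0, w1 = params.stump_window
    inwin = (proj >= w0) & (proj <= w1)
    cross = rel[:, 0] * d0[1] - rel[:, 1] * d0[0]
    side_a = stump[inwin & (cross > 0)]
    side_b = stump[inwin & (cross < 0)]
    if len(side_a) < params.min_side_points or len(side_b) < params.min_side_points:
        raise MeasurementError("extract_cortex_contours",
                               "medial stump cortices not found in the "
                               "lateral-opening window")

    ymax = lat_pts[:, 1].max()
    ymin = lat_pts[:, 1].min()
    gt_ventral = lat_pts[lat_pts[:, 1] >= ymax - 8.0]
    dorsal_lt = lat_pts[lat_pts[:, 1] <= ymin + 8.0]
    if len(gt_ventral) == 0:
        raise MeasurementError("extract_cortex_contours",
                               "greater trochanter ventral cortex not found")
    if len(dorsal_lt) == 0:
        raise MeasurementError("extract_cortex_contours",
                               "dorsal lesser trochanter cortex not found")
    return ContourSet(head_arc=head_arc, stump_side_a=side_a, stump_side_b=side_b,
                      gt_ventral=gt_ventral, dorsal_lt=dorsal_lt,
                      medial_points=med_pts, lateral_points=lat_pts,
                      head_center_2d=h2, head_disc_radius=r_disc)


# ---------------------------------------------------------------------------
# stage 4: the geometric construction


def _fit_side_line(points, along):
    """Total-least-squares line through cortex points, oriented along
    the rough stump direction."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    d = vt[0]
    if np.dot(d, along) < 0:
        d = -d
    return Line2D(point=c, direction=d)


def _medial_axis_circles(cs: ContourSet, params: MeasureParams):
    """Head circle and lateral-opening circle; their connecting line is
    the medial (head fragment) neck axis."""
    head_circle = fit_circle(cs.head_arc)
    d0 = unit(np.vstack([cs.stump_side_a, cs.stump_side_b]).mean(axis=0)
              - cs.head_center_2d)
    l1 = _fit_side_line(cs.stump_side_a, d0)
    l2 = _fit_side_line(cs.stump_side_b, d0)
    dm = unit(l1.direction + l2.direction)
    anchor = cs.head_center_2d + 0.5 * (params.stump_window[0]
                                        + params.stump_window[1]) * d0
    f1 = l1.at(l1.project_coordinate(anchor))
    f2 = l2.at(l2.project_coordinate(anchor))
    pm = 0.5 * (f1 + f2)
    half_width = 0.5 * float(np.linalg.norm(f1 - f2))
    midline = Line2D(point=pm, direction=dm)
    t_open = float(np.sqrt(max(head_circle.radius ** 2 - half_width ** 2,
                               (0.35 * head_circle.radius) ** 2)))
    target = head_circle.center + t_open * dm
    opening_center = midline.at(midline.project_coordinate(target))
    opening = Circle2D(center=opening_center, radius=half_width)
    return head_circle, opening


def measure_torsion(volume: Volume, hints: MeasurementHints,
                    params: MeasureParams = None) -> TorsionMeasurement:
    """Run the full direct measurement and return the construction."""
    params = params or MeasureParams()
    frame = align_neck_frame(volume, hints.head_center, hints.neck_direction,
                             params, superior=hints.superior,
                             anterior=hints.anterior)
    slab = extract_axial_slab(volume, frame, params.slab_thickness,
                              extent=params.slab_extent,
                              spacing=params.in_plane_spacing)
    cs = extract_cortex_contours(slab, params.threshold, params)

    try:
        tangent = supporting_tangent(cs.gt_ventral, (0.0, 1.0))
        dorsal_support = supporting_tangent(cs.dorsal_lt, (0.0, -1.0))
        parallel = parallel_through_point(tangent, dorsal_support.point)
    except ValueError as e:
        raise MeasurementError("tangent_construction", str(e)) from e

    try:
        head_circle, opening = _medial_axis_circles(cs, params)
        medial_axis = axis_from_centers(head_circle, opening)
    except ValueError as e:
        raise MeasurementError("medial_axis", str(e)) from e

    try:
        tau0 = tangent.project_coordinate(opening.center)
        tau_lat = np.array([tangent.project_coordinate(p)
                            for p in cs.lateral_points])
        s_dir = 1.0 if (tangent.project_coordinate(cs.lateral_points.mean(axis=0))
                        >= tau0) else -1.0
        tau_end = s_dir * np.max(s_dir * tau_lat)
        off = tangent.signed_distance(parallel.point)
        nhat = np.array([-tangent.direction[1], tangent.direction[0]])
        neck_circles = []
        for f in params.neck_stations:
            tau = tau0 + f * (tau_end - tau0)
            anchor = tangent.point + tau * tangent.direction + 0.5 * off * nhat
            neck_circles.append(inscribed_circle_between_lines(tangent, parallel,
                                                               anchor))
        lateral_axis = axis_from_centers(*neck_circles)
    except ValueError as e:
        raise MeasurementError("lateral_axis", str(e)) from e

    pair = AxisPair(medial_axis=medial_axis, lateral_axis=lateral_axis)
    ang = angle_between_axes(pair, (0.0, 1.0))
    if not params.anteversion_positive:
        ang = -ang
    slice_ref = {
        "frame_origin": frame.origin.tolist(),
        "frame_axes": frame.axes.tolist(),
        "head_center": frame.head_center.tolist(),
        "neck_direction": frame.neck_direction.tolist(),
        "slab_thickness": slab.slab_thickness,
        "in_plane_spacing": slab.spacing.tolist(),
        "threshold": params.threshold,
    }
    return TorsionMeasurement(angle_deg=float(ang),
                              circles=(head_circle, opening, *neck_circles),
                              tangent=tangent, parallel=parallel, axes=pair,
                              slice_ref=slice_ref, contours=cs)
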