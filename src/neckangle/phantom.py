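"""Parametric proximal-femur voxel phantom with a basicervical osteotomy.

Emulates the physical study setup: a radiopaque femur model cut at the
base of the neck and mounted in a goniometer that rotates the medial
(head) fragment about a displacement axis roughly parallel to the shaft
-- slightly angulated in the frontal view -- in a range of 30 degrees
retroversion to 30 degrees anteversion.

The anatomy is deliberately stylised (sphere head, frustum neck,
ellipsoid trochanters, cylinder shaft) so that every landmark has a
closed-form ground truth.  The proximal geometry is arranged so that a
single near-axial 5-mm section guided down by the calcar shows all four
landmarks of the direct measurement simultaneously: the femoral head
disc, both neck stumps, the ventral cortex of the greater trochanter
and the dorsal cortex of the lesser trochanter.

World frame is LPS: for the default left femur, medial is -x, anterior
is -y, superior +z.  The neck base sits at the world origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import MeasurementSeries
from .util import rotation_matrix, signed_angle_about, unit
from .volume import Volume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and acquisition parameters of the phantom.

    Lengths in mm, angles in degrees, intensities in arbitrary CT-like
    units.  ``set_angle`` is the goniometer displacement: anteversion
    positive, 10-degree increments over [-30, +30] in the study.
    """

    set_angle: float = 0.0
    head_radius: float = 24.0
    neck_length: float = 50.0
    neck_radius_medial: float = 13.0
    neck_radius_lateral: float = 17.0
    shaft_radius: float = 14.0
    greater_trochanter_semiaxes: tuple = (14.0, 16.0, 18.0)
    lesser_trochanter_semiaxes: tuple = (9.0, 10.0, 12.0)
    greater_trochanter_center: tuple = (13.0, -6.0, 6.0)
    lesser_trochanter_center: tuple = (6.0, 19.0, 0.0)
    gt_facet_offset: float = 19.5
    native_anteversion: float = 0.0
    neck_elevation_deg: float = 30.0
    osteotomy_offset: float = 40.0
    displacement_axis_tilt_deg: float = 10.0
    kerf: float = 4.0
    relief_cut: bool = True
    cortical_thickness: float = 2.0
    shaft_z_range: tuple = (-40.0, 8.0)
    side: str = "left"
    voxel_spacing: tuple = (0.6, 0.6, 1.0)
    cortical_value: float = 1200.0
    trabecular_value: float = 300.0
    background_value: float = 0.0
    noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if not -30.0 <= self.set_angle <= 30.0:
            raise ValueError("set_angle must lie in [-30, +30] degrees")
        if not all(s > 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")
        if not self.head_radius > self.neck_radius_medial > 0:
            raise ValueError("require head_radius > neck_radius_medial > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not 0 < self.osteotomy_offset < self.neck_length:
            raise ValueError("osteotomy must cut the neck between head and base")

    # -- derived ground-truth geometry (pre-displacement) ---------------------
    @property
    def _sx(self) -> float:
        """Mirror factor: +1 for a left femur, -1 for a right one."""
        return 1.0 if self.side == "left" else -1.0

    @property
    def medial_direction(self) -> np.ndarray:
        """Unit vector along the intact neck axis, base toward head."""
        e = np.radians(self.neck_elevation_deg)
        av = np.radians(self.native_anteversion)
        return np.array([-self._sx * np.cos(e) * np.cos(av),
                         -np.cos(e) * np.sin(av),
                         np.sin(e)])

    @property
    def head_center(self) -> np.ndarray:
        """Head center of the intact (undisplaced) femur; neck base is
        the world origin."""
        return self.neck_length * self.medial_direction

    @property
    def osteotomy_center(self) -> np.ndarray:
        return self.head_center - self.osteotomy_offset * self.medial_direction

    @property
    def displacement_axis(self) -> np.ndarray:
        """Goniometer axis: shaft direction tilted laterally in the
        frontal view, through the osteotomy-plane center."""
        t = np.radians(self.displacement_axis_tilt_deg)
        lat_ax = unit(-np.append(self.medial_direction[:2], 0.0))
        return unit(np.cos(t) * np.array([0.0, 0.0, 1.0]) + np.sin(t) * lat_ax)

    @property
    def displacement_rotation(self) -> np.ndarray:
        """Rotation applied to the medial fragment.  The handedness flip
        for a right femur keeps anteversion = head tilting anteriorly."""
        return rotation_matrix(self.displacement_axis, self._sx * self.set_angle)


def _sdf_sphere(X, Y, Z, c, r):
    return np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) - r


def _sdf_ellipsoid(X, Y, Z, c, s):
    # Standard scaled approximation d = k0 (k0 - 1) / k1; accurate near
    # the surface, which is all the cortical shell needs.
    x, y, z = X - c[0], Y - c[1], Z - c[2]
    k0 = np.sqrt((x / s[0]) ** 2 + (y / s[1]) ** 2 + (z / s[2]) ** 2)
    k1 = np.sqrt((x / s[0] ** 2) ** 2 + (y / s[1] ** 2) ** 2 + (z / s[2] ** 2) ** 2)
    return np.where(k1 > 1e-12, k0 * (k0 - 1.0) / np.maximum(k1, 1e-12),
                    -np.min(s))


def _sdf_cylinder_z(X, Y, Z, cx, cy, r, z0, z1):
    radial = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2) - r
    return np.maximum(radial, np.maximum(z0 - Z, Z - z1))


def _sdf_frustum(X, Y, Z, a, b, ra, rb):
    """Tapered cylinder from point ``a`` (radius ra) to ``b`` (radius rb),
    with planar caps."""
    a = np.asarray(a, float)
    d = np.asarray(b, float) - a
    L = np.linalg.norm(d)
    dh = d / L
    px, py, pz = X - a[0], Y - a[1], Z - a[2]
    t = px * dh[0] + py * dh[1] + pz * dh[2]
    tc = np.clip(t, 0.0, L)
    perp2 = (px - tc * dh[0]) ** 2 + (py - tc * dh[1]) ** 2 + (pz - tc * dh[2]) ** 2
    rt = ra + (rb - ra) * (tc / L)
    radial = np.sqrt(np.maximum(perp2, 0.0)) - rt
    return np.maximum(radial, np.maximum(-t, t - L))


def _mirror(v, sx):
    v = np.asarray(v, float).copy()
    v[0] *= sx
    return v


def _neck_end_radius(spec: PhantomSpec, neck_end: float) -> float:
    """Frustum radius extrapolated linearly past the neck base, so the
    taper stays head->base even though the solid blends into the
    trochanteric mass."""
    slope = (spec.neck_radius_lateral - spec.neck_radius_medial) / spec.neck_length
    return spec.neck_radius_medial + slope * neck_end


def build_phantom(spec: PhantomSpec) -> Volume:
    """Voxelise the osteotomised phantom at the requested displacement.

    Returns a :class:`Volume` whose ``meta`` carries the full ground
    truth (landmarks, axes, set angle) used by tests and the validation
    harness.  Raises if the displaced fragments would physically collide.
    """
    sx = spec._sx
    u_med = spec.medial_direction
    u_lat = -u_med
    head = spec.head_center
    o = spec.osteotomy_center
    R = spec.displacement_rotation
    gt_c = _mirror(spec.greater_trochanter_center, sx)
    lt_c = _mirror(spec.lesser_trochanter_center, sx)

    # grid extents with margin, covering the head through all set angles
    margin = 5.0
    swing = spec.osteotomy_offset + spec.head_radius
    xs_lo = min(head[0] - spec.head_radius, gt_c[0] - spec.greater_trochanter_semiaxes[0],
                -spec.shaft_radius, o[0] - swing * 0.55)
    xs_hi = max(head[0] + spec.head_radius, gt_c[0] + spec.greater_trochanter_semiaxes[0],
                lt_c[0] + spec.lesser_trochanter_semiaxes[1], spec.shaft_radius,
                o[0] + swing * 0.55)
    y_hi = max(spec.head_radius + swing * np.sin(np.radians(31.0)),
               lt_c[1] + spec.lesser_trochanter_semiaxes[1])
    z_lo = spec.shaft_z_range[0]
    z_hi = head[2] + spec.head_radius
    lo = np.array([min(xs_lo, xs_hi) - margin, -y_hi - margin, z_lo - margin])
    hi = np.array([max(xs_lo, xs_hi) + margin, y_hi + margin, z_hi + margin])

    sp = np.asarray(spec.voxel_spacing, float)
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    X = (lo[0] + np.arange(shape[0]) * sp[0])[:, None, None]
    Y = (lo[1] + np.arange(shape[1]) * sp[1])[None, :, None]
    Z = (lo[2] + np.arange(shape[2]) * sp[2])[None, None, :]

    neck_end = spec.neck_length + 8.0  # blends into the trochanteric mass

    # ventral facet of the greater trochanter: the flat "frontal cortex"
    # along which the tangent is drawn; parallel to shaft and neck axis
    u_ax_lat = unit(np.append(u_lat[:2], 0.0))
    n_facet = np.cross(np.array([0.0, 0.0, 1.0]), u_ax_lat)
    if n_facet[1] > 0:  # orient anterior (-y in LPS)
        n_facet = -n_facet

    def lateral_union(X, Y, Z):
        gt = np.maximum(
            _sdf_ellipsoid(X, Y, Z, gt_c, spec.greater_trochanter_semiaxes),
            X * n_facet[0] + Y * n_facet[1] - spec.gt_facet_offset)
        parts = [
            _sdf_frustum(X, Y, Z, head, head + neck_end * u_lat,
                         spec.neck_radius_medial, _neck_end_radius(spec, neck_end)),
            _sdf_cylinder_z(X, Y, Z, 0.0, 0.0, spec.shaft_radius, *spec.shaft_z_range),
            gt,
            _sdf_ellipsoid(X, Y, Z, lt_c, spec.lesser_trochanter_semiaxes),
        ]
        out = parts[0]
        for p in parts[1:]:
            np.minimum(out, p, out=out)
        return out

    def medial_union(X, Y, Z):
        return np.minimum(
            _sdf_sphere(X, Y, Z, head, spec.head_radius),
            _sdf_frustum(X, Y, Z, head, head + neck_end * u_lat,
                         spec.neck_radius_medial, _neck_end_radius(spec, neck_end)))

    # osteotomy: the trochanters must remain on the lateral fragment
    for name, c in (("greater", gt_c), ("lesser", lt_c)):
        if np.dot(c - o, u_lat) <= 0:
            raise ValueError(f"osteotomy is distal to the {name} trochanter; "
                             "not a basicervical cut")

    side_coord = (X - o[0]) * u_lat[0] + (Y - o[1]) * u_lat[1] + (Z - o[2]) * u_lat[2]
    lat_sdf = np.maximum(lateral_union(X, Y, Z), spec.kerf / 2.0 - side_coord)

    def medial_fragment_sdf(rot):
        """Medial fragment (cut at the osteotomy) in displaced position,
        evaluated by pulling coordinates back through ``rot``."""
        Xp = rot[0, 0] * (X - o[0]) + rot[1, 0] * (Y - o[1]) + rot[2, 0] * (Z - o[2]) + o[0]
        Yp = rot[0, 1] * (X - o[0]) + rot[1, 1] * (Y - o[1]) + rot[2, 1] * (Z - o[2]) + o[1]
        Zp = rot[0, 2] * (X - o[0]) + rot[1, 2] * (Y - o[1]) + rot[2, 2] * (Z - o[2]) + o[2]
        side_p = (Xp - o[0]) * u_lat[0] + (Yp - o[1]) * u_lat[1] + (Zp - o[2]) * u_lat[2]
        mu = medial_union(Xp, Yp, Zp)
        return np.maximum(mu, side_p + spec.kerf / 2.0), mu

    med_sdf, med_union = medial_fragment_sdf(R)

    # Relief cut: like the physical jig, the lateral fragment must clear
    # the head fragment over the whole goniometer range, not just at the
    # current setting.  Carve the medial fragment's swept volume (with a
    # small clearance) out of the lateral fragment once; the lateral
    # fragment is then identical at every set angle.
    if spec.relief_cut:
        axis = spec.displacement_axis
        clearance = 2.5
        for phi in np.arange(-31.0, 31.01, 4.0):
            sw, _ = medial_fragment_sdf(rotation_matrix(axis, spec._sx * phi))
            np.maximum(lat_sdf, clearance - sw, out=lat_sdf)

    med_in = med_sdf < 0
    lat_in = lat_sdf < 0
    n_overlap = int(np.count_nonzero(med_in & lat_in))
    n_bone = int(np.count_nonzero(med_in | lat_in))
    if n_bone == 0:
        raise ValueError("phantom is empty; check the geometry parameters")
    if n_overlap > 0.001 * n_bone:
        raise ValueError(
            f"medial and lateral fragments collide ({n_overlap} voxels); "
            "physically impossible configuration")

    values = np.full(tuple(shape), float(spec.background_value), dtype=np.float32)
    values[lat_in] = spec.trabecular_value
    values[lat_in & (lat_sdf > -spec.cortical_thickness)
           & (lateral_union(X, Y, Z) > -spec.cortical_thickness)] = spec.cortical_value
    values[med_in] = spec.trabecular_value
    values[med_in & (med_union > -spec.cortical_thickness)] = spec.cortical_value
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values += rng.normal(0.0, spec.noise_sd, size=values.shape).astype(np.float32)

    head_displaced = R @ (head - o) + o
    meta = {
        "phantom": True,
        "set_angle_deg": spec.set_angle,
        "native_anteversion_deg": spec.native_anteversion,
        "side": spec.side,
        "head_center": head_displaced,
        "head_center_undisplaced": head,
        "neck_axis_direction": u_lat,          # lateral fragment, head -> base
        "medial_fragment_axis": R @ u_med,     # displaced head fragment, base -> head
        "osteotomy_center": o,
        "displacement_axis": spec.displacement_axis,
        "neck_elevation_deg": spec.neck_elevation_deg,
        "head_radius": spec.head_radius,
        "osteotomy_offset": spec.osteotomy_offset,
        "neck_length": spec.neck_length,
        "kerf": spec.kerf,
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "overlap_voxels": n_overlap,
        "bone_voxels": n_bone,
    }
    return Volume(values=values, spacing=sp, origin=lo, meta=meta)


def ground_truth_angle(meta: dict) -> float:
    """Signed torsion between the fragments from stored landmarks:
    the angle between the medial-fragment axis and the intact neck axis,
    measured about the displacement axis (anteversion positive)."""
    sgn = 1.0 if meta.get("side", "left") == "left" else -1.0
    return sgn * signed_angle_about(
        -np.asarray(meta["neck_axis_direction"], float),
        np.asarray(meta["medial_fragment_axis"], float),
        np.asarray(meta["displacement_axis"], float))


def simulate_goniometer_series(levels=(-30, -20, -10, 10, 20, 30),
                               replicates: int = 10,
                               raters: int = 2,
                               rater_bias=None,
                               rater_noise_sd: float = 1.5,
                               seed: int = 0) -> MeasurementSeries:
    """Statistical stand-in for the imaging loop.

    Draws ``measured = set + bias_rater + eps`` with
    ``eps ~ Normal(0, rater_noise_sd^2)`` and shuffles the measurement
    order within each rater, emulating the blinded randomized protocol
    (ten repetitions per level and rater in the study).  Drives the
    statistics module without building or measuring volumes.
    """
    if replicates < 1 or raters < 2:
        raise ValueError("need at least 1 replicate and 2 raters")
    if rater_noise_sd < 0:
        raise ValueError("rater_noise_sd must be non-negative")
    levels = list(levels)
    if not levels:
        raise ValueError("need at least one displacement level")
    bias = np.zeros(raters) if rater_bias is None else np.asarray(rater_bias, float)
    if bias.shape != (raters,):
        raise ValueError("rater_bias must provide one bias per rater")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, raters + 1):
        cells = [(lvl, rep) for lvl in levels for rep in range(1, replicates + 1)]
        order = rng.permutation(len(cells))
        for pos, k in enumerate(order, start=1):
            lvl, rep = cells[k]
            measured = lvl + bias[r - 1] + rng.normal(0.0, rater_noise_sd)
            rows.append((r, rep, float(lvl), float(measured), pos))
    df = pd.DataFrame(rows, columns=["rater", "replicate", "set_angle_deg",
                                     "measured_angle_deg", "measurement_order"])
    return MeasurementSeries(df.sort_values(["rater", "set_angle_deg", "replicate"],
                                            ignore_index=True))
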