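"""Tests of the section frame, slab extraction, contour labeling and the
end-to-end torsion measurement."""

import numpy as np
import pytest

from neckangle import (MeasureParams, MeasurementError, MeasurementHints,
                       PhantomSpec, SectionFrame, Volume, align_neck_frame,
                       build_phantom, extract_axial_slab,
                       extract_cortex_contours, measure_torsion)
from neckangle.util import project_out, rotation_matrix, unit

from conftest import STUDY_SPACING

PARAMS = MeasureParams()


def hints_for(vol):
    return MeasurementHints.from_phantom_meta(vol.meta)


def signed_inplane(frame, v_ref, v):
    n = frame.axes[2]
    a = unit(project_out(v_ref, n))
    b = unit(project_out(v, n))
    return np.degrees(np.arctan2(np.dot(np.cross(a, b), n), np.dot(a, b)))


class TestAlignNeckFrame:
    def test_exact_hints_recover_ground_truth_axes(self, phantom_zero):
        meta = phantom_zero.meta
        frame = align_neck_frame(phantom_zero, meta["head_center"],
                                 meta["neck_axis_direction"], PARAMS)
        # head center refined to within half a voxel
        assert np.linalg.norm(frame.head_center - np.asarray(meta["head_center"])) \
            < 0.5 * max(STUDY_SPACING)
        # e1 within 1 degree of the projected ground-truth neck axis
        target = unit(project_out(-np.asarray(meta["neck_axis_direction"]),
                                  frame.axes[2]))
        ang = np.degrees(np.arccos(np.clip(abs(frame.axes[0] @ target), -1, 1)))
        assert ang < 1.0

    def test_refinement_fixes_perturbed_hints(self, phantom_zero):
        meta = phantom_zero.meta
        u = rotation_matrix((0, 0, 1), 2.0) @ np.asarray(meta["neck_axis_direction"])
        frame = align_neck_frame(phantom_zero,
                                 np.asarray(meta["head_center"]) + [1.0, -1.0, 0.5],
                                 u, PARAMS)
        target = unit(project_out(-np.asarray(meta["neck_axis_direction"]),
                                  frame.axes[2]))
        ang = np.degrees(np.arccos(np.clip(abs(frame.axes[0] @ target), -1, 1)))
        assert ang < 0.5

    def test_frame_is_right_handed_orthonormal(self, phantom_zero):
        meta = phantom_zero.meta
        frame = align_neck_frame(phantom_zero, meta["head_center"],
                                 meta["neck_axis_direction"], PARAMS)
        A = frame.axes
        assert np.allclose(A @ A.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(A) > 0.999

    def test_rotated_volume_gives_rotated_frame(self, phantom_zero):
        """Equivariance: rotating the scan 90 degrees about the world z
        axis (with matching hints) rotates the frame identically."""
        meta = phantom_zero.meta
        Rz = rotation_matrix((0, 0, 1), 90.0)
        rotated = Volume(values=phantom_zero.values, spacing=phantom_zero.spacing,
                         origin=Rz @ phantom_zero.origin,
                         direction=Rz @ phantom_zero.direction)
        f0 = align_neck_frame(phantom_zero, meta["head_center"],
                              meta["neck_axis_direction"], PARAMS)
        f1 = align_neck_frame(rotated, Rz @ np.asarray(meta["head_center"]),
                              Rz @ np.asarray(meta["neck_axis_direction"]),
                              PARAMS, superior=(0, 0, 1),
                              anterior=Rz @ np.array([0.0, -1.0, 0.0]))
        assert np.allclose(f1.origin, Rz @ f0.origin, atol=1e-6)
        assert np.allclose(f1.axes, f0.axes @ Rz.T, atol=1e-6)

    def test_hint_outside_volume_errors(self, phantom_zero):
        with pytest.raises(MeasurementError):
            align_neck_frame(phantom_zero, (500.0, 0.0, 0.0), (1, 0, 0), PARAMS)


class TestExtractAxialSlab:
    def frame_at(self, center):
        return SectionFrame(origin=center, axes=np.eye(3))

    def test_uniform_volume_gives_uniform_slab(self):
        vol = Volume(values=np.full((40, 40, 40), 7.0), spacing=(1, 1, 1),
                     origin=(-20, -20, -20))
        slab = extract_axial_slab(vol, self.frame_at((0, 0, 0)), 5.0,
                                  extent=((-10, 10), (-10, 10)))
        assert np.allclose(slab.values, 7.0)

    def test_single_voxel_thickness_matches_plane_resample(self):
        rng = np.random.default_rng(0)
        vol = Volume(values=rng.normal(size=(30, 30, 30)), spacing=(1, 1, 1),
                     origin=(-15, -15, -15))
        slab = extract_axial_slab(vol, self.frame_at((0, 0, 0)), thickness=1.0,
                                  extent=((-5, 5), (-5, 5)))
        from scipy import ndimage

        xs = np.arange(-5, 5.5, 1.0)
        ys = np.arange(-5, 5.5, 1.0)
        pts = np.stack(np.meshgrid(xs, ys, indexing="xy"), axis=-1)
        world = np.concatenate([pts, np.zeros((*pts.shape[:2], 1))], axis=-1)
        idx = vol.world_to_index(world.reshape(-1, 3)).T
        expected = ndimage.map_coordinates(vol.values.astype(float), idx,
                                           order=1).reshape(len(ys), len(xs))
        assert np.allclose(slab.values, expected)

    def test_sphere_projects_to_equatorial_disk(self):
        sp = 1.0
        shape = (60, 60, 60)
        grid = [np.arange(s) * sp - 30 + sp / 2 for s in shape]
        X, Y, Z = np.meshgrid(*grid, indexing="ij")
        values = (np.sqrt(X ** 2 + Y ** 2 + Z ** 2) < 20.0) * 1000.0
        vol = Volume(values=values, spacing=(sp, sp, sp),
                     origin=(-30 + sp / 2, -30 + sp / 2, -30 + sp / 2))
        slab = extract_axial_slab(vol, self.frame_at((0, 0, 0)), 5.0,
                                  extent=((-28, 28), (-28, 28)))
        ys, xs = np.nonzero(slab.values > 500.0)
        xmm = slab.origin2d[0] + xs * slab.spacing[0]
        ymm = slab.origin2d[1] + ys * slab.spacing[1]
        radius = np.max(np.hypot(xmm, ymm))
        assert abs(radius - 20.0) <= 1.0 + sp

    def test_slab_outside_volume_errors(self):
        vol = Volume(values=np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        with pytest.raises(MeasurementError):
            extract_axial_slab(vol, self.frame_at((500, 500, 500)), 5.0,
                               extent=((-5, 5), (-5, 5)))


class TestContourExtraction:
    def slab_of(self, vol):
        meta = vol.meta
        frame = align_neck_frame(vol, meta["head_center"],
                                 meta["neck_axis_direction"], PARAMS)
        return extract_axial_slab(vol, frame, 5.0, extent=PARAMS.slab_extent)

    def test_head_arc_lies_on_ground_truth_circle(self, phantom_zero):
        slab = self.slab_of(phantom_zero)
        # at the half-cortical threshold the contour tracks the true surface
        cs = extract_cortex_contours(slab, 600.0, PARAMS)
        h2_true = slab.frame.to_plane(np.asarray(phantom_zero.meta["head_center"]))
        dz = abs((np.asarray(phantom_zero.meta["head_center"]) - slab.frame.origin)
                 @ slab.frame.axes[2])
        r_true = np.sqrt(phantom_zero.meta["head_radius"] ** 2 - dz ** 2)
        dist = np.linalg.norm(cs.head_arc - h2_true, axis=1)
        assert np.max(np.abs(dist - r_true)) <= max(STUDY_SPACING)

    def test_all_landmarks_present(self, phantom_zero):
        slab = self.slab_of(phantom_zero)
        cs = extract_cortex_contours(slab, PARAMS.threshold, PARAMS)
        for arr in (cs.head_arc, cs.stump_side_a, cs.stump_side_b,
                    cs.gt_ventral, cs.dorsal_lt):
            assert len(arr) > 0
        # ventral cortex is ventral of the dorsal cortex
        assert cs.gt_ventral[:, 1].min() > cs.dorsal_lt[:, 1].max()

    def test_threshold_above_cortex_errors(self, phantom_zero):
        slab = self.slab_of(phantom_zero)
        with pytest.raises(MeasurementError, match="no cortex"):
            extract_cortex_contours(slab, 10_000.0, PARAMS)

    def test_noise_does_not_change_labels(self, phantom_zero):
        meta = phantom_zero.meta
        noisy = build_phantom(PhantomSpec(set_angle=0.0,
                                          voxel_spacing=STUDY_SPACING,
                                          noise_sd=0.05 * 1200.0, seed=3))
        m_clean = measure_torsion(phantom_zero, hints_for(phantom_zero), PARAMS)
        m_noisy = measure_torsion(noisy, hints_for(noisy), PARAMS)
        for cs in (m_clean.contours, m_noisy.contours):
            for arr in (cs.head_arc, cs.stump_side_a, cs.stump_side_b,
                        cs.gt_ventral, cs.dorsal_lt):
                assert len(arr) > 0
        assert abs(m_noisy.angle_deg - m_clean.angle_deg) < 0.75


class TestMeasureTorsion:
    def test_null_displacement(self, phantom_zero):
        m = measure_torsion(phantom_zero, hints_for(phantom_zero), PARAMS)
        assert abs(m.angle_deg) <= 1.0

    def test_ten_degree_level_within_study_range(self):
        """The 10-degree anteversion level must land inside the span of
        values the human raters reported for that level (9.60-12.40)."""
        vol = build_phantom(PhantomSpec(set_angle=10.0, voxel_spacing=STUDY_SPACING,
                                        noise_sd=25.0, seed=21))
        m = measure_torsion(vol, hints_for(vol), PARAMS)
        assert 9.60 <= m.angle_deg <= 12.40

    def test_monotone_in_set_angle(self):
        measured = []
        for th in (-30.0, -20.0, -10.0, 10.0, 20.0, 30.0):
            vol = build_phantom(PhantomSpec(set_angle=th,
                                            voxel_spacing=(1.0, 1.0, 1.0),
                                            noise_sd=25.0, seed=77))
            measured.append(measure_torsion(vol, hints_for(vol), PARAMS).angle_deg)
        assert np.all(np.diff(measured) > 0)

    def test_deterministic(self, phantom_p10_noisy):
        h = hints_for(phantom_p10_noisy)
        m1 = measure_torsion(phantom_p10_noisy, h, PARAMS)
        m2 = measure_torsion(phantom_p10_noisy, h, PARAMS)
        assert m1.angle_deg == m2.angle_deg
        for c1, c2 in zip(m1.circles, m2.circles):
            assert np.array_equal(c1.center, c2.center) and c1.radius == c2.radius
        assert np.array_equal(m1.tangent.point, m2.tangent.point)

    def test_mirrored_volume_with_flipped_convention_negates(self, phantom_p20):
        """A mirrored scan (right femur) measured with the flipped sign
        convention yields the negated angle."""
        m_left = measure_torsion(phantom_p20, hints_for(phantom_p20), PARAMS)
        vol = phantom_p20
        nx = vol.shape[0]
        mirrored = Volume(values=vol.values[::-1, :, :].copy(),
                          spacing=vol.spacing,
                          origin=np.array([-(vol.origin[0]
                                             + (nx - 1) * vol.spacing[0]),
                                           vol.origin[1], vol.origin[2]]))
        flip = np.array([-1.0, 1.0, 1.0])
        h = MeasurementHints(
            head_center=flip * np.asarray(vol.meta["head_center"]),
            neck_direction=flip * np.asarray(vol.meta["neck_axis_direction"]))
        m_flip = measure_torsion(mirrored, h,
                                 MeasureParams(anteversion_positive=False))
        assert abs(m_flip.angle_deg - (-m_left.angle_deg)) < 0.2

    def test_construction_is_audit_complete(self, phantom_zero):
        m = measure_torsion(phantom_zero, hints_for(phantom_zero), PARAMS)
        assert len(m.circles) == 4
        # lateral axis runs through both inscribed circle centers and is
        # parallel to the tangent
        n1, n2 = m.neck_circles
        assert abs(m.axes.lateral_axis.signed_distance(n1.center)) < 1e-9
        assert abs(m.axes.lateral_axis.signed_distance(n2.center)) < 1e-9
        cross = (m.tangent.direction[0] * m.axes.lateral_axis.direction[1]
                 - m.tangent.direction[1] * m.axes.lateral_axis.direction[0])
        assert abs(cross) < 1e-9
        # medial axis passes through the head and opening circle centers
        assert abs(m.axes.medial_axis.signed_distance(m.head_circle.center)) < 1e-9
        assert abs(m.axes.medial_axis.signed_distance(m.opening_circle.center)) < 1e-9
        d = m.to_dict()
        assert set(d) >= {"angle_deg", "circles", "tangent", "parallel",
                          "medial_axis", "lateral_axis", "slice_ref"}
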