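"""Quartet-plane fits and helical descriptors."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gqpull.geometry import (
    DegenerateGeometryError,
    fit_quartet_plane,
    frame_stem_geometry,
    geometry_table,
    planarity,
    rise,
    stem_axis,
    step_twist,
    step_twist_matched,
    tilt,
)
from gqpull.synth import StemBlueprint, build_ideal_stem, make_deformation_traj


def brute_force_planarity(points):
    """Independent oracle: minimise the RMSD of point-plane distances over
    all plane orientations (spherical parametrisation of the normal)."""
    pts = np.asarray(points, float)
    centred = pts - pts.mean(axis=0)

    def rmsd(angles):
        th, ph = angles
        n = np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        return np.sqrt(np.mean((centred @ n) ** 2))

    best = np.inf
    for th0 in np.linspace(0.1, np.pi - 0.1, 6):
        for ph0 in np.linspace(0, 2 * np.pi, 6, endpoint=False):
            res = minimize(rmsd, [th0, ph0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
            best = min(best, res.fun)
    return best


class TestPlaneFit:
    def test_coplanar_points_have_zero_planarity(self, rng):
        xy = rng.normal(size=(16, 2))
        pts = np.column_stack([xy, np.zeros(16)])
        plane = fit_quartet_plane(pts)
        assert plane.planarity == pytest.approx(0.0, abs=1e-9)
        assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(plane.centroid, pts.mean(axis=0))

    def test_alternating_offsets_give_rmsd_of_offset(self):
        # points on a circle with alternating +/-0.5 A displacements: no
        # tilted plane can absorb the pattern, so the RMSD is exactly 0.5
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        xy = 4.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        z = np.where(np.arange(16) % 2 == 0, 0.5, -0.5)
        plane = fit_quartet_plane(np.column_stack([xy, z]))
        assert plane.planarity == pytest.approx(0.5, abs=1e-6)

    def test_planarity_matches_brute_force_plane_search(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(20, 3)) * [4.0, 4.0, 0.4]
            plane = fit_quartet_plane(pts)
            assert plane.planarity == pytest.approx(
                brute_force_planarity(pts), abs=1e-6
            )

    def test_planarity_equals_sigma3_over_sqrt_n_and_residual_rmsd(self, rng):
        pts = rng.normal(size=(24, 3)) * [5, 5, 0.3]
        plane = fit_quartet_plane(pts)
        assert plane.planarity == pytest.approx(
            plane.singular_values[2] / np.sqrt(24), abs=1e-12
        )
        resid = plane.signed_distance(pts)
        assert plane.planarity == pytest.approx(
            np.sqrt(np.mean(resid**2)), abs=1e-9
        )

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(20, 3)) * [4, 4, 0.5]
        p0 = planarity(fit_quartet_plane(pts))
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(size=3) * 10
            p1 = planarity(fit_quartet_plane(pts @ rot.T + shift))
            assert p1 == pytest.approx(p0, abs=1e-8)

    def test_buckled_base_increases_planarity(self, ideal_4q):
        traj, topo = ideal_4q
        from gqpull.topology import GUANINE_BASE_ATOMS

        pts = np.vstack(
            [
                traj.residue_coords(0, rid, GUANINE_BASE_ATOMS)
                for rid in topo.quartets[0]
            ]
        )
        flat = fit_quartet_plane(pts).planarity
        buckled = pts.copy()
        rot = Rotation.from_euler("x", 30, degrees=True)
        buckled[:11] = rot.apply(buckled[:11] - buckled[:11].mean(axis=0)) + \
            buckled[:11].mean(axis=0)
        assert fit_quartet_plane(buckled).planarity > flat

    @pytest.mark.parametrize(
        "pts",
        [
            np.zeros((2, 3)),
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float),
            np.array([[0, 0, 0], [1, 0, 0], [np.nan, 0, 0]]),
        ],
        ids=["too-few", "collinear", "non-finite"],
    )
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(DegenerateGeometryError):
            fit_quartet_plane(pts)


class TestTiltRiseAxisTwist:
    def test_identical_planes_have_zero_tilt(self, rng):
        pts = rng.normal(size=(20, 3)) * [4, 4, 0.2]
        p = fit_quartet_plane(pts)
        assert tilt(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_15_degree_tilt(self, rng):
        pts = np.column_stack([rng.normal(size=(16, 2)) * 4, np.zeros(16)])
        pa = fit_quartet_plane(pts)
        rot = Rotation.from_euler("x", 15, degrees=True)
        pb = fit_quartet_plane(rot.apply(pts))
        t = tilt(pa, pb)
        # normal sign from SVD is arbitrary: accept the co-oriented angle
        assert min(t, 180 - t) == pytest.approx(15.0, abs=1e-6)

    def test_tilt_matches_arccos_oracle_and_symmetry(self, rng):
        for _ in range(10):
            a = fit_quartet_plane(rng.normal(size=(15, 3)) * [4, 4, 0.3])
            b = fit_quartet_plane(rng.normal(size=(15, 3)) * [4, 4, 0.3])
            expect = np.degrees(
                np.arccos(np.clip(np.dot(a.normal, b.normal), -1, 1))
            )
            assert tilt(a, b) == pytest.approx(expect, abs=1e-9)
            assert tilt(b, a) == pytest.approx(tilt(a, b), abs=1e-12)

    def test_rise_of_translated_quartet(self, rng):
        pts = np.column_stack([rng.normal(size=(30, 2)) * 4, np.zeros(30)])
        shifted = pts + np.array([0, 0, 3.3])
        assert rise(pts, shifted) == pytest.approx(3.3, abs=1e-6)
        assert rise(pts, pts.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_rise_bisector_variant_agrees_for_parallel_quartets(self, rng):
        pts = np.column_stack([rng.normal(size=(30, 2)) * 4, np.zeros(30)])
        shifted = pts + np.array([0, 0, 3.3])
        assert rise(pts, shifted, method="bisector") == pytest.approx(
            3.3, abs=1e-6
        )

    def test_stem_axis_two_quartets_is_centroid_difference(self):
        c = np.array([[0.0, 0, 0], [1.0, 2.0, 2.0]])
        axis = stem_axis(c)
        expect = c[1] / np.linalg.norm(c[1])
        assert np.allclose(axis, expect, atol=1e-9)

    def test_stem_axis_equivariant_under_rotation(self, rng):
        c = np.column_stack(
            [rng.normal(size=(5, 2)) * 0.1, np.arange(5) * 3.4]
        )
        axis = stem_axis(c)
        rot = Rotation.random(rng=rng).as_matrix()
        assert np.allclose(stem_axis(c @ rot.T), rot @ axis, atol=1e-6)

    def test_step_twist_reference_vector_form(self):
        axis = np.array([0.0, 0.0, 1.0])
        ca, cb = np.zeros(3), np.array([0, 0, 3.4])
        ra = np.array([5.0, 0, 0])
        rot = Rotation.from_euler("z", 30, degrees=True)
        rb = rot.apply(ra) + cb
        assert step_twist(ra, ca, rb, cb, axis) == pytest.approx(30, abs=1e-9)
        # left-handed rotation gives the opposite sign
        rb2 = Rotation.from_euler("z", -30, degrees=True).apply(ra) + cb
        assert step_twist(ra, ca, rb2, cb, axis) == pytest.approx(-30, abs=1e-9)

    def test_step_twist_degenerate_reference_raises(self):
        axis = np.array([0.0, 0.0, 1.0])
        with pytest.raises(DegenerateGeometryError):
            step_twist_matched(
                np.array([[0, 0, 1.0]]), np.array([[0, 0, 2.0]]),
                np.zeros(3), np.zeros(3), axis,
            )


class TestStemRecovery:
    def test_ideal_stem_descriptors(self, ideal_4q):
        traj, topo = ideal_4q
        geo = frame_stem_geometry(traj, 0, topo)
        assert np.allclose(geo.step_twist, 30.0, atol=1e-6)
        assert np.allclose(geo.step_rise, 3.4, atol=1e-6)
        assert np.allclose(geo.step_tilt, 0.0, atol=1e-6)
        assert geo.total_twist == pytest.approx(90.0, abs=1e-6)
        assert geo.handedness == 1

    def test_mirror_stem_has_opposite_twist(self):
        traj, topo = build_ideal_stem(StemBlueprint(n_quartets=3,
                                                    twist_per_step=-30))
        geo = frame_stem_geometry(traj, 0, topo)
        assert geo.total_twist == pytest.approx(-60.0, abs=1e-6)
        assert geo.handedness == -1

    def test_per_step_twist_schedule_recovered_exactly(self):
        bp = StemBlueprint(n_quartets=4)
        sched = np.tile([25.0, 30.0, 35.0], (5, 1))
        traj, topo, _ = make_deformation_traj(bp, 5, twist_schedule=sched)
        for f in range(5):
            geo = frame_stem_geometry(traj, f, topo)
            assert np.allclose(geo.step_twist, [25, 30, 35], atol=1e-6)

    def test_twist_ramp_recovered_every_frame(self):
        bp = StemBlueprint(n_quartets=3)
        tw = np.linspace(30, 20, 40)
        traj, topo, truth = make_deformation_traj(bp, 40, twist_schedule=tw)
        for f in (0, 13, 39):
            geo = frame_stem_geometry(traj, f, topo)
            assert np.allclose(
                geo.step_twist, truth.frames["step_twist_deg"][f], atol=1e-6
            )

    def test_rigid_motion_invariance_of_descriptors(self, ideal_4q, rng):
        traj, topo = ideal_4q
        ref = frame_stem_geometry(traj, 0, topo)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 20
        moved = traj.coords[0] @ rot.T + shift
        from gqpull.trajectory import Trajectory

        traj2 = Trajectory(atoms=traj.atoms, coords=moved[None],
                           times=np.zeros(1))
        geo = frame_stem_geometry(traj2, 0, topo)
        assert np.allclose(geo.step_twist, ref.step_twist, atol=1e-8)
        assert np.allclose(geo.step_rise, ref.step_rise, atol=1e-8)
        assert np.allclose(geo.step_tilt, ref.step_tilt, atol=1e-8)
        assert np.allclose(
            geo.planarity, ref.planarity, atol=1e-8
        )

    def test_noisy_recovery_within_stated_tolerances(self):
        # recovery from a noisy trajectory averages the per-frame estimates
        bp = StemBlueprint(n_quartets=4, rise_per_step=3.4, twist_per_step=30)
        traj, topo, _ = make_deformation_traj(bp, 10, noise_sd=0.2, seed=5)
        geos = [frame_stem_geometry(traj, f, topo) for f in range(10)]
        mean_twist = np.mean([g.step_twist for g in geos], axis=0)
        mean_rise = np.mean([g.step_rise for g in geos], axis=0)
        assert np.allclose(mean_twist, 30.0, atol=1.0)
        assert np.allclose(mean_rise, 3.4, atol=0.1)

    def test_geometry_table_layout(self, ideal_3q):
        traj, topo = ideal_3q
        table = geometry_table(traj, topo)
        assert len(table) == traj.n_frames * 3
        assert table.loc[table["index"] == 0, "step_twist_deg"].isna().all()
        assert (table["handedness"] == 1).all()
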