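"""Spring-force reconstruction, decomposition, feo and rupture extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqpull.forces import (
    PN_PER_KJ_MOL_NM,
    EdgeVectors,
    ForceSeries,
    PullingSchedule,
    decompose,
    edge_unit_vectors,
    force_edge_overlap,
    out_of_plane_angle,
    rupture_force,
    spring_force,
    transition_forces,
)
from gqpull.geometry import fit_quartet_plane

AVOGADRO = 6.02214076e23


def test_unit_conversion_constant_against_avogadro():
    # 1 kJ/mol/nm = 1e3 J / N_A / 1e-9 m, expressed in pN
    expect = 1e3 / AVOGADRO / 1e-9 * 1e12
    assert PN_PER_KJ_MOL_NM == pytest.approx(expect, rel=1e-6)


class TestSpringForce:
    @pytest.mark.parametrize(
        "stretch_nm,expect_pN",
        [(0.0, 0.0), (1.0, 298.9), (0.5, 149.4)],
    )
    def test_force_magnitude_from_stretch(self, stretch_nm, expect_pN):
        sched = PullingSchedule(force_constant=180.0, pull_speed=0.0,
                                d0=2.0 + stretch_nm)
        series = spring_force(np.array([0.0]), np.array([2.0]), sched)
        assert series.force_pN[0] == pytest.approx(expect_pN, abs=0.05)

    def test_moving_center_and_direction_vector(self):
        sched = PullingSchedule(force_constant=180.0, pull_speed=5.4, d0=2.0)
        t = np.array([0.0, 100.0])          # ns
        d = np.array([2.0, 2.0])
        series = spring_force(t, d, sched, anchor_direction=[0.0, 0.0, 1.0])
        # after 100 ns at 5.4 nm/us the center moved 0.54 nm
        assert series.center_nm[1] == pytest.approx(2.54)
        assert series.force_pN[1] == pytest.approx(
            180 * 0.54 * PN_PER_KJ_MOL_NM, rel=1e-9
        )
        assert np.allclose(series.force_vec[1],
                           [0, 0, series.force_pN[1]])

    def test_compressive_episode_is_negative(self):
        sched = PullingSchedule(force_constant=180.0, pull_speed=0.0, d0=1.0)
        series = spring_force(np.array([0.0]), np.array([1.5]), sched)
        assert series.force_pN[0] < 0
        assert series.magnitude[0] > 0

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            ForceSeries(
                time_ns=[0, 1, 1], distance_nm=[1, 1, 1],
                center_nm=[1, 1, 1], force_pN=[0, 0, 0],
            )


class TestOutOfPlaneAngle:
    def setup_method(self):
        pts = np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
             np.sin(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
             np.zeros(12)]
        )
        self.planes = [fit_quartet_plane(pts * 4)]

    def test_in_plane_force(self):
        assert out_of_plane_angle([1.0, 2.0, 0.0], self.planes) == \
            pytest.approx(0.0, abs=1e-9)

    def test_normal_force_is_90(self):
        beta = out_of_plane_angle([0.0, 0.0, 3.0], self.planes)
        assert abs(beta) == pytest.approx(90.0, abs=1e-9)

    def test_constructed_30_degree_elevation(self):
        n = self.planes[0].normal
        f = np.array([np.cos(np.radians(30)), 0, 0]) + \
            np.sin(np.radians(30)) * n
        assert abs(out_of_plane_angle(f, self.planes)) == pytest.approx(
            30.0, abs=1e-6
        )

    def test_zero_force_returns_nan_not_exception(self):
        assert np.isnan(out_of_plane_angle([0.0, 0.0, 0.0], self.planes))


class TestDecompose:
    @pytest.mark.parametrize(
        "f,beta,fh,fv",
        [(5.0, 90.0, 0.0, 5.0), (5.0, 0.0, 5.0, 0.0)],
    )
    def test_limits(self, f, beta, fh, fv):
        dec = decompose(f, beta)
        assert dec.f_horizontal == pytest.approx(fh, abs=1e-9)
        assert dec.f_vertical == pytest.approx(fv, abs=1e-9)

    def test_ratio_is_tangent(self):
        assert decompose(7.7, 45.0).vh_ratio == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(decompose(1.0, 90.0).vh_ratio)

    @given(
        f=st.floats(0, 1e4),
        beta=st.floats(-89.9, 89.9),
    )
    @settings(max_examples=300, derandomize=True)
    def test_pythagorean_identity(self, f, beta):
        dec = decompose(f, beta)
        assert dec.f_horizontal**2 + dec.f_vertical**2 == pytest.approx(
            f**2, rel=1e-8, abs=1e-12
        )


class TestForceEdgeOverlap:
    def test_aligned_with_wc_edge(self):
        edges = EdgeVectors(u_wc=np.array([1.0, 0, 0]),
                            u_h=np.array([0, 1.0, 0]))
        assert force_edge_overlap([5.0, 0, 0], edges) == pytest.approx(1.0)
        assert force_edge_overlap([0, 5.0, 0], edges) == pytest.approx(-1.0)

    def test_hand_example(self):
        edges = EdgeVectors(u_wc=np.array([1.0, 0, 0]),
                            u_h=np.array([0, 1.0, 0]))
        assert force_edge_overlap([3.0, 4.0, 0.0], edges) == pytest.approx(
            -0.2, abs=1e-12
        )

    def test_zero_force_is_nan(self):
        edges = EdgeVectors(u_wc=np.array([1.0, 0, 0]),
                            u_h=np.array([0, 1.0, 0]))
        assert np.isnan(force_edge_overlap([0.0, 0, 0], edges))

    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=9))
    @settings(max_examples=300, derandomize=True)
    def test_bounded_in_minus_one_one(self, vals):
        f = np.array(vals[:3])
        u1, u2 = np.array(vals[3:6]), np.array(vals[6:9])
        if np.linalg.norm(f) < 1e-6:
            return
        if np.linalg.norm(u1) < 1e-6 or np.linalg.norm(u2) < 1e-6:
            return
        edges = EdgeVectors(u_wc=u1 / np.linalg.norm(u1),
                            u_h=u2 / np.linalg.norm(u2))
        feo = force_edge_overlap(f, edges)
        assert -1.0 - 1e-12 <= feo <= 1.0 + 1e-12

    def test_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        f = rng.normal(size=3) * 100
        u1 = rng.normal(size=3)
        u2 = rng.normal(size=3)
        u1, u2 = u1 / np.linalg.norm(u1), u2 / np.linalg.norm(u2)
        base = force_edge_overlap(f, EdgeVectors(u_wc=u1, u_h=u2))
        for _ in range(5):
            rot = Rotation.random(rng=rng)
            rotated = force_edge_overlap(
                rot.apply(f),
                EdgeVectors(u_wc=rot.apply(u1), u_h=rot.apply(u2)),
            )
            assert rotated == pytest.approx(base, abs=1e-9)


class TestEdgeVectors:
    def test_ideal_quartet_edges_lie_in_plane(self, ideal_4q):
        traj, topo = ideal_4q
        level = 0
        g = topo.quartets[level][0]
        wc_partner = topo.quartets[level][1]
        h_partner = topo.quartets[level][3]

        def atom_map(rid):
            names = ("N1", "N2", "O6", "N7")
            return dict(zip(names, traj.residue_coords(0, rid, names)))

        edges = edge_unit_vectors(atom_map(g), atom_map(wc_partner),
                                  atom_map(h_partner))
        # the stem axis is z; a planar quartet's H-bond edges stay in-plane
        assert abs(edges.u_wc[2]) < 0.05
        assert abs(edges.u_h[2]) < 0.05

    def test_bisector_oracle(self):
        g = {"N1": np.zeros(3), "N2": np.array([1.0, 0, 0]),
             "O6": np.array([0.0, 1, 0]), "N7": np.array([1.0, 1, 0])}
        wc = {"O6": np.array([0.0, -2, 0]), "N7": np.array([1.0, -2, 0])}
        h = {"N1": np.array([0.0, 3, 0]), "N2": np.array([1.0, 3, 0])}
        edges = edge_unit_vectors(g, wc, h)
        v1 = (wc["O6"] - g["N1"]) / np.linalg.norm(wc["O6"] - g["N1"])
        v2 = (wc["N7"] - g["N2"]) / np.linalg.norm(wc["N7"] - g["N2"])
        expect = (v1 + v2) / np.linalg.norm(v1 + v2)
        assert np.allclose(edges.u_wc, expect, atol=1e-9)

    def test_missing_partner_atom_raises(self):
        g = {"N1": np.zeros(3), "N2": np.ones(3), "O6": np.ones(3),
             "N7": np.zeros(3)}
        with pytest.raises(KeyError):
            edge_unit_vectors(g, {"O6": np.ones(3)}, g)


def brute_force_windowed_max(mag, times, t_event, window):
    """Independent oracle: enumerate every contiguous window."""
    dt = times[1] - times[0]
    m = int(np.floor(window / dt + 1e-9)) + 1
    best = -np.inf
    for i in range(len(mag) - m + 1):
        if times[i + m - 1] <= t_event + 1e-12:
            best = max(best, mag[i:i + m].mean())
    return best


class TestRuptureForce:
    def _series(self, force, dt=0.01):
        t = np.arange(len(force)) * dt
        return ForceSeries(time_ns=t, distance_nm=np.ones_like(t),
                           center_nm=np.ones_like(t), force_pN=force)

    def test_constant_plateau(self):
        series = self._series(np.full(1001, 350.0))
        assert rupture_force(series, 10.0, window_ns=2.0) == pytest.approx(
            350.0
        )

    def test_linear_ramp_matches_discretized_oracle(self):
        t = np.arange(0, 100.0001, 0.01)
        force = 4.0 * t                      # 0 -> 400 pN over 100 ns
        series = self._series(force)
        got = rupture_force(series, 100.0, window_ns=2.0)
        expect = brute_force_windowed_max(np.abs(force), t, 100.0, 2.0)
        assert got == pytest.approx(expect, abs=1e-9)
        assert got == pytest.approx(396.0, abs=0.5)

    def test_random_trace_matches_oracle(self, rng):
        force = rng.normal(200, 50, 600)
        series = self._series(force)
        got = rupture_force(series, 5.0, window_ns=2.0)
        expect = brute_force_windowed_max(np.abs(force), series.time_ns,
                                          5.0, 2.0)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_noisy_plateau_within_standard_error(self, rng):
        sigma, n_window = 10.0, 201
        force = rng.normal(350.0, sigma, 2001)
        series = self._series(force)
        got = rupture_force(series, 20.0, window_ns=2.0)
        assert abs(got - 350.0) < 3 * sigma / np.sqrt(n_window) + 3 * sigma * \
            0.1  # max over ~1800 windows inflates the estimate slightly

    def test_maximality_over_all_windows(self, rng):
        force = rng.normal(100, 30, 500)
        series = self._series(force)
        got = rupture_force(series, 4.0, window_ns=1.0)
        dt = 0.01
        m = int(np.floor(1.0 / dt + 1e-9)) + 1
        mag = np.abs(force)
        for i in range(len(force) - m + 1):
            if series.time_ns[i + m - 1] <= 4.0:
                assert got >= mag[i:i + m].mean() - 1e-12

    def test_errors(self):
        series = self._series(np.full(101, 10.0))
        with pytest.raises(ValueError):
            rupture_force(series, -1.0)
        with pytest.raises(ValueError):
            rupture_force(series, 0.5, window_ns=2.0)


class TestTransitionForces:
    def test_constant_trace_single_event(self):
        t = np.arange(0, 10.001, 0.01)
        series = ForceSeries(time_ns=t, distance_nm=np.ones_like(t),
                             center_nm=np.ones_like(t),
                             force_pN=np.full_like(t, 123.0))
        out = transition_forces(series, [5.0], window_ns=2.0)
        assert out[0] == pytest.approx(123.0)

    def test_two_plateau_trace(self):
        t = np.arange(0, 20.001, 0.01)
        force = np.where(t < 10, 300.0, 150.0)
        series = ForceSeries(time_ns=t, distance_nm=np.ones_like(t),
                             center_nm=np.ones_like(t), force_pN=force)
        out = transition_forces(series, [8.0, 18.0], window_ns=2.0)
        assert out[0] == pytest.approx(300.0)
        assert out[1] == pytest.approx(150.0)

    def test_trailing_window_oracle(self, rng):
        t = np.arange(0, 10.001, 0.01)
        force = rng.normal(200, 20, len(t))
        series = ForceSeries(time_ns=t, distance_nm=np.ones_like(t),
                             center_nm=np.ones_like(t), force_pN=force)
        te = 6.0
        out = transition_forces(series, [te], window_ns=2.0)
        mask = (t >= te - 2.0 - 1e-12) & (t <= te + 1e-12)
        assert out[0] == pytest.approx(np.abs(force[mask]).mean(), abs=1e-9)

    def test_truncated_window_warns(self):
        t = np.arange(0, 5.001, 0.01)
        series = ForceSeries(time_ns=t, distance_nm=np.ones_like(t),
                             center_nm=np.ones_like(t),
                             force_pN=np.full_like(t, 50.0))
        with pytest.warns(UserWarning, match="truncated"):
            transition_forces(series, [1.0], window_ns=2.0)
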