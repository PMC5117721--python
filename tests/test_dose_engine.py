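"""Per-CP dose engine: geometry, attenuation, linearity, noise."""

import numpy as np
import pytest

from quaarc.dose_engine import (BeamModel, ContributionMatrix, CylinderMedium,
                                DoseGrid, GridMedium, add_statistical_noise,
                                build_contribution_matrix, cp_dose,
                                cp_dose_at_points, load_cp_doses,
                                save_cp_doses)
from quaarc.phantom_scroll import build_phantom
from quaarc.plan_log import ControlPoint, DiscretizedArc

from conftest import open_field_cp


def closed_cp(angle=0.0):
    return ControlPoint(index=0, gantry_angle=angle,
                        leaf_a=np.zeros(4), leaf_b=np.zeros(4),
                        mu=10.0, cumulative_mu=10.0)


def small_grid(n=24, vs=5.0):
    origin = -np.array([n - 1, n - 1, n - 1]) * vs / 2
    return DoseGrid.empty(origin, (vs, vs, vs), (n, n, n))


class TestCpDose:
    def test_closed_aperture_zero_transmission_gives_zero_dose(self):
        model = BeamModel(leaf_transmission=0.0)
        pts = np.array([[0.0, 0.0, 0.0], [10.0, 5.0, -3.0]])
        dose = cp_dose_at_points(pts, closed_cp(), model)
        np.testing.assert_allclose(dose, 0.0, atol=1e-15)

    def test_closed_aperture_with_transmission_leaks(self):
        model = BeamModel(leaf_transmission=0.015)
        dose = cp_dose_at_points(np.array([[0.0, 0.0, 0.0]]),
                                 closed_cp(), model)
        assert 0 < dose[0] <= 0.015 * model.mu_to_gy * 1.01

    def test_gantry_rotation_rotates_the_pattern(self, beam_model):
        """Dose at gantry 90 on rotated points equals dose at gantry 0 on
        the originals (cylindrically symmetric medium)."""
        medium = CylinderMedium(radius=100.0, z_min=-140, z_max=140)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-60, 60, (200, 3))
        cp0 = open_field_cp(angle=0.0)
        cp90 = open_field_cp(angle=90.0)
        # rotate points by +90 deg about z (x <- y, y <- -x)
        rot = np.column_stack([pts[:, 1], -pts[:, 0], pts[:, 2]])
        d0 = cp_dose_at_points(pts, cp0, beam_model, medium)
        d90 = cp_dose_at_points(rot, cp90, beam_model, medium)
        np.testing.assert_allclose(d90, d0, rtol=1e-9, atol=1e-15)

    def test_attenuation_follows_the_exponential_law(self, beam_model):
        """On the central ray, dose(d2)/dose(d1) = exp(-mu_eff*rho*(d2-d1))."""
        medium = CylinderMedium(radius=100.0, density=1.19)
        cp = open_field_cp(angle=0.0)
        # central ray at gantry 0 runs along -y; depth below surface y=100
        y1, y2 = 50.0, -50.0   # depths 50 and 150 mm
        d = cp_dose_at_points(np.array([[0.0, y1, 0.0], [0.0, y2, 0.0]]),
                              cp, beam_model, medium)
        expected = np.exp(-beam_model.attenuation_coeff * 1.19 * (y1 - y2))
        assert d[1] / d[0] == pytest.approx(expected, rel=1e-9)

    def test_grid_medium_matches_analytic_cylinder(self, beam_model):
        """Ray-marched radiological depth on a voxelized cylinder agrees
        with the closed-form chord within the marching tolerance."""
        _, density = build_phantom("small", voxel_size=(2.5, 2.5, 2.5))
        gm = GridMedium(density)
        cm = CylinderMedium(radius=100.0, z_min=-140, z_max=140)
        cp = open_field_cp(angle=0.0)
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 50.0, 0.0], [30.0, -20.0, 10.0]])
        dg = cp_dose_at_points(pts, cp, beam_model, gm)
        dc = cp_dose_at_points(pts, cp, beam_model, cm)
        np.testing.assert_allclose(dg, dc, rtol=0.02)

    def test_full_grid_equals_pointwise(self, beam_model):
        grid = small_grid(12)
        cp = open_field_cp(angle=30.0)
        g = cp_dose(grid, cp, beam_model)
        pts = grid.voxel_centers()
        np.testing.assert_array_equal(
            g.values.ravel(), cp_dose_at_points(pts, cp, beam_model))


class TestContributionMatrix:
    def _arc(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        mus = rng.uniform(5, 15, n)
        cps = tuple(
            open_field_cp(angle=float(i * 36 % 360), mu=float(m), index=i,
                          cumulative=float(mus[: i + 1].sum()))
            for i, m in enumerate(mus)
        )
        return DiscretizedArc(cps, "coarse", float(mus.sum()))

    def test_one_cp_linearity(self, beam_model, one_cp_arc):
        pts = np.array([[0.0, 20.0, 0.0], [5.0, -30.0, 10.0]])
        C = build_contribution_matrix(one_cp_arc, pts, beam_model)
        total = C.dose_for_weights(np.ones(1))
        per_mu = cp_dose_at_points(pts, one_cp_arc.control_points[0],
                                   beam_model)
        np.testing.assert_allclose(total, 100.0 * per_mu, rtol=1e-12)

    def test_splitting_a_cp_preserves_total_dose(self, beam_model):
        cp = open_field_cp(mu=50.0)
        half = open_field_cp(mu=25.0)
        arc1 = DiscretizedArc((cp,), "coarse", 50.0)
        arc2 = DiscretizedArc(
            (half,
             ControlPoint(1, half.gantry_angle, half.leaf_a, half.leaf_b,
                          25.0, 50.0)), "coarse", 50.0)
        pts = np.array([[0.0, 10.0, 0.0]])
        d1 = build_contribution_matrix(arc1, pts, beam_model).dose_for_weights([1.0])
        d2 = build_contribution_matrix(arc2, pts, beam_model).dose_for_weights([1.0, 1.0])
        np.testing.assert_allclose(d1, d2, rtol=1e-14)

    def test_matrix_sum_matches_direct_accumulation(self, beam_model):
        arc = self._arc(10)
        pts = np.random.default_rng(2).uniform(-40, 40, (50, 3))
        C = build_contribution_matrix(arc, pts, beam_model)
        direct = np.zeros(len(pts))
        for cp in arc.control_points:
            direct += cp.mu * cp_dose_at_points(pts, cp, beam_model)
        assert np.max(np.abs(C.dose_for_weights(np.ones(10)) - direct)) < 1e-10

    def test_empty_rows_rejected(self, beam_model, one_cp_arc):
        with pytest.raises(ValueError):
            build_contribution_matrix(one_cp_arc, np.empty((0, 3)), beam_model)


class TestStatisticalNoise:
    def test_zero_sigma_is_identity(self):
        g = small_grid(8)
        g.values[:] = 2.0
        out = add_statistical_noise(g, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, g.values)

    def test_same_seed_bit_identical(self):
        g = small_grid(8)
        g.values[:] = 1.5
        a = add_statistical_noise(g, 0.01, seed=42)
        b = add_statistical_noise(g, 0.01, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_sd_matches_the_stated_law(self):
        """1 % relative noise on a 2 Gy voxel: sample SD 0.02 Gy +/- 3 %."""
        g = DoseGrid.empty((0, 0, 0), (1, 1, 1), (10000, 1, 1))
        g.values[:] = 2.0
        out = add_statistical_noise(g, 0.01, seed=7)
        sd = out.values.std()
        assert sd == pytest.approx(0.02, rel=0.03)

    def test_clipping_keeps_dose_non_negative(self):
        g = small_grid(8)
        g.values[:] = 1e-6
        out = add_statistical_noise(g, 0.05, seed=3)
        assert np.all(out.values >= 0)

    def test_invalid_sigma_rejected(self):
        g = small_grid(4)
        with pytest.raises(ValueError):
            add_statistical_noise(g, 0.5, seed=0)


def test_cp_dose_directory_round_trip(tmp_path, beam_model):
    grid = small_grid(10)
    cps = [open_field_cp(angle=a) for a in (0.0, 120.0)]
    grids = [cp_dose(grid, cp, beam_model) for cp in cps]
    save_cp_doses(str(tmp_path / "doses"), grids)
    back = load_cp_doses(str(tmp_path / "doses"))
    assert len(back) == 2
    for g0, g1 in zip(grids, back):
        np.testing.assert_allclose(g0.values, g1.values, rtol=1e-6)
        np.testing.assert_array_equal(g0.origin, g1.origin)
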