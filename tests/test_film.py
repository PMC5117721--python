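"""Film calibration, multichannel conversion, lateral correction and
rigid registration."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from quaarc.film import (DEFAULT_RESPONSE, CalibrationCurve, FilmScan,
                         RigidTransform2D, apply_rigid, film_response,
                         fit_calibration, lateral_correction,
                         multichannel_dose, register_rigid_mi)
from quaarc.synthetic_data import default_calibration

DOSES_16 = np.linspace(0.0, 400.0, 16)


def synth_values(doses, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for ch, p in DEFAULT_RESPONSE.items():
        v = film_response(doses, *p)
        if noise_sd > 0:
            v = v + noise_sd * v * rng.standard_normal(v.shape)
        out[ch] = v
    return out


class TestCalibration:
    def test_noiseless_fit_recovers_parameters(self):
        cal = fit_calibration(DOSES_16, synth_values(DOSES_16))
        for ch, (a, b, c) in DEFAULT_RESPONSE.items():
            fa, fb, fc = cal.params[ch]
            assert fa == pytest.approx(a, rel=1e-4)
            assert fb == pytest.approx(b, rel=1e-4)
            assert fc == pytest.approx(c, rel=1e-4)

    def test_zero_dose_point_closed_form(self):
        cal = fit_calibration(DOSES_16, synth_values(DOSES_16))
        a, b, c = cal.params["green"]
        assert cal.response("green", 0.0) == pytest.approx(a - b / c)

    def test_noisy_inverse_within_2_cgy_rms(self):
        """0.5 % scanner noise on 16 calibration points: green-channel
        inverse doses stay within 2 cGy RMS (100 seeded replicates)."""
        errs = []
        for seed in range(100):
            vals = synth_values(DOSES_16, noise_sd=0.005, seed=seed)
            cal = fit_calibration(DOSES_16, vals)
            clean = film_response(DOSES_16, *DEFAULT_RESPONSE["green"])
            back = cal.inverse("green", clean)
            errs.append(np.sqrt(np.mean((back - DOSES_16) ** 2)))
        assert np.median(errs) < 2.0

    def test_too_few_points_rejected(self):
        d = np.linspace(0, 400, 10)
        with pytest.raises(ValueError):
            fit_calibration(d, synth_values(d))

    def test_non_monotone_channel_rejected_with_warning(self):
        vals = synth_values(DOSES_16)
        vals["red"] = vals["red"].copy()
        vals["red"][5] = vals["red"][2] + 0.2   # break monotonicity
        with pytest.warns(UserWarning, match="non-monotone"):
            cal = fit_calibration(DOSES_16, vals)
        assert "red" not in cal.params
        assert "green" in cal.params

    def test_inverse_consistency_across_the_range(self):
        cal = fit_calibration(DOSES_16, synth_values(DOSES_16))
        doses = np.linspace(0, 400, 41)
        for ch in cal.params:
            back = cal.inverse(ch, cal.response(ch, doses))
            np.testing.assert_allclose(back, doses, atol=1e-6)

    def test_json_round_trip(self):
        cal = default_calibration()
        back = CalibrationCurve.from_json(cal.to_json())
        assert back.params == cal.params


class TestMultichannel:
    def _scan_from_dose(self, dose_cgy, delta=0.0):
        channels = {
            ch: film_response(dose_cgy, *p) * (1.0 + delta)
            for ch, p in DEFAULT_RESPONSE.items()
        }
        return FilmScan(channels)

    def test_noiseless_round_trip_within_0p1_cgy(self):
        rng = np.random.default_rng(5)
        dose = ndimage.gaussian_filter(rng.uniform(20, 380, (24, 24)), 2)
        scan = self._scan_from_dose(dose)
        rec, delta, valid = multichannel_dose(scan, default_calibration())
        assert np.all(valid)
        assert np.max(np.abs(rec - dose)) < 0.1
        assert np.max(np.abs(delta)) < 1e-3

    def test_common_mode_disturbance_is_absorbed(self):
        dose = np.full((8, 8), 150.0)
        scan = self._scan_from_dose(dose, delta=0.02)
        rec, delta, valid = multichannel_dose(scan, default_calibration())
        assert np.max(np.abs(rec - 150.0)) < 0.5
        assert np.mean(delta) == pytest.approx(0.02, abs=2e-3)

    def test_unexposed_film_reads_zero(self):
        scan = self._scan_from_dose(np.zeros((6, 6)))
        rec, _, _ = multichannel_dose(scan, default_calibration())
        assert np.max(np.abs(rec)) < 0.5

    def test_disturbance_off_reduces_to_green_inversion(self):
        dose = np.linspace(10, 390, 64).reshape(8, 8)
        scan = self._scan_from_dose(dose)
        cal = default_calibration()
        rec, delta, _ = multichannel_dose(scan, cal, allow_disturbance=False)
        direct = cal.inverse("green", scan.channels["green"])
        np.testing.assert_allclose(rec, direct, atol=1e-9)
        assert np.all(delta == 0)

    def test_out_of_range_pixels_flagged_invalid(self):
        scan = self._scan_from_dose(np.full((4, 4), 100.0))
        for ch in scan.channels:
            scan.channels[ch][0, 0] = 0.999   # brighter than any dose
        _, _, valid = multichannel_dose(scan, default_calibration())
        assert not valid[0, 0]
        assert valid[1:, :].all()


class TestLateralCorrection:
    def test_flat_profile_is_identity(self):
        scan = FilmScan({c: np.random.default_rng(0).random((10, 12))
                         for c in ("red", "green", "blue")})
        out = lateral_correction(scan, np.ones(12))
        for c in scan.channels:
            np.testing.assert_array_equal(out.channels[c], scan.channels[c])

    def test_parabolic_profile_round_trip(self):
        rng = np.random.default_rng(1)
        scan = FilmScan({c: rng.random((10, 16)) for c in ("red", "green",
                                                           "blue")})
        xs = np.linspace(-1, 1, 16)
        prof = 1.0 - 0.03 * xs**2
        distorted = FilmScan({c: v * prof[None, :]
                              for c, v in scan.channels.items()})
        restored = lateral_correction(distorted, prof)
        for c in scan.channels:
            assert np.max(np.abs(restored.channels[c] - scan.channels[c])) \
                < 1e-6

    def test_uniform_film_restored_within_0p2_pct(self):
        xs = np.linspace(-1, 1, 32)
        prof = 1.0 - 0.03 * xs**2          # 3 % falloff at the edges
        uniform = np.full((8, 32), 0.6)
        distorted = FilmScan({c: uniform * prof[None, :]
                              for c in ("red", "green", "blue")})
        restored = lateral_correction(distorted, prof)
        for c in restored.channels:
            assert np.max(np.abs(restored.channels[c] / 0.6 - 1)) < 0.002

    def test_bad_profile_rejected(self):
        scan = FilmScan({"green": np.ones((4, 6))})
        with pytest.raises(ValueError):
            lateral_correction(scan, np.zeros(6))
        with pytest.raises(ValueError):
            lateral_correction(scan, np.ones(5))


def _test_image(n=72, seed=2):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.random((n, n)), 5)
    img -= img.min()
    return img / img.max()


class TestRegistration:
    def test_identical_images_give_identity(self):
        img = _test_image()
        t = register_rigid_mi(img, img, shift_bound_px=4, rot_bound_deg=2)
        assert t.shift == (0.0, 0.0)
        assert t.rotation_deg == 0.0

    def test_known_shift_recovered(self):
        img = _test_image()
        moved = ndimage.shift(img, (2.0, 0.0), order=1)
        t = register_rigid_mi(moved, img, shift_bound_px=4, rot_bound_deg=1)
        assert t.shift[0] == pytest.approx(-2.0, abs=0.5)
        assert t.shift[1] == pytest.approx(0.0, abs=0.5)

    def test_known_rotation_recovered(self):
        img = _test_image()
        moved = ndimage.rotate(img, 1.5, reshape=False, order=1)
        t = register_rigid_mi(moved, img, shift_bound_px=2, rot_bound_deg=3)
        assert t.rotation_deg == pytest.approx(-1.5, abs=0.25)

    def test_random_transforms_recovered(self):
        """Seeded property: drawn shifts/rotations within bounds come back
        within half a pixel and a quarter degree."""
        img = _test_image(seed=9)
        rng = np.random.default_rng(17)
        for _ in range(3):
            sy, sx = rng.uniform(-2, 2, 2).round(1)
            rot = round(float(rng.uniform(-1.5, 1.5)), 2)
            moved = apply_rigid(img, RigidTransform2D((sy, sx), rot))
            t = register_rigid_mi(moved, img, shift_bound_px=4,
                                  rot_bound_deg=3)
            # applying the recovered transform to `moved` must undo it
            # (judged on the interior, away from zero-filled borders)
            undone = apply_rigid(moved, t)
            core = np.s_[12:-12, 12:-12]
            assert np.mean((undone[core] - img[core]) ** 2) \
                < np.mean((moved[core] - img[core]) ** 2)
            assert abs(t.shift[0] + sy) <= 0.5 + 0.26 * abs(rot)
            assert abs(t.shift[1] + sx) <= 0.5 + 0.26 * abs(rot)

    def test_boundary_optimum_warns(self):
        img = _test_image()
        moved = ndimage.shift(img, (5.0, 0.0), order=1)
        with pytest.warns(UserWarning, match="boundary"):
            register_rigid_mi(moved, img, shift_bound_px=3, rot_bound_deg=1)
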