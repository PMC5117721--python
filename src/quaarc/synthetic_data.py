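"""Seeded end-to-end scenario generator with known ground truth.

A *scenario* bundles everything one verification run needs, all derived
reproducibly from (parameters, seed): a VMAT-like arc plan, the delivery
log the machine "actually" produced (with an injected smooth per-CP MU
drift — the ground truth x* the adjustment should recover — plus leaf and
gantry jitter), the phantom, the contribution matrices on the measurement
points and the patient grid, the true delivered doses, synthetic film
scans and a chamber reading.

The MU drift is a smooth low-frequency process (a sum of up to three random
sinusoids over the arc), not white noise: real delivery errors are
correlated along the arc, and that correlation is what the lateral-overlap
adjustment exploits.  The delivery timescale is compressed — one 0.25 s
beam-on log record per plan control point by default — so the coarse
discretization aligns one-to-one with the plan CPs and the ground truth is
defined per solved CP (``records_per_cp`` restores denser logs).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .dose_engine import BeamModel, ContributionMatrix, build_contribution_matrix
from .film import (DEFAULT_RESPONSE, CalibrationCurve, FilmScan, film_response)
from .phantom_scroll import PhantomModel, ScrollImage, build_phantom
from .plan_log import (ControlPoint, DeliveryLog, DiscretizedArc, LogRecord,
                       discretize)

__all__ = [
    "ErrorModel",
    "Scenario",
    "make_arc_plan",
    "emulate_delivery",
    "default_calibration",
    "scroll_to_film_scan",
    "synthesize_measurements",
    "make_scenario",
]


@dataclass(frozen=True)
class ErrorModel:
    """Magnitudes of the injected delivery errors (all >= 0; zeros give an
    exact replay of the plan — the static control case)."""

    mu_drift: float = 0.05          # fractional amplitude of the smooth drift
    leaf_jitter_mm: float = 0.0
    angle_jitter_deg: float = 0.0


def make_arc_plan(n_cp: int = 48, arc_span: float = 360.0,
                  total_mu: float = 200.0, modulation: float = 0.5,
                  n_leaf_pairs: int = 8, field_half_width: float = 40.0,
                  seed: int = 0) -> DiscretizedArc:
    """A synthetic single-arc plan: equi-spaced CPs with smoothly varying
    random apertures and MU.

    ``modulation`` in [0, 1] scales both the aperture variability and the MU
    non-uniformity; 0 gives identical apertures and uniform MU.
    """
    if n_cp < 2:
        raise ValueError("a plan needs at least two control points")
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, arc_span, n_cp, endpoint=False) + arc_span / n_cp
    # smooth random MU pattern: uniform + low-frequency modulation
    t = np.linspace(0, 2 * np.pi, n_cp, endpoint=False)
    mu_shape = np.ones(n_cp)
    for k in (1, 2, 3):
        mu_shape += modulation * 0.2 / k * np.sin(k * t + rng.uniform(0, 2 * np.pi))
    mu_shape = np.clip(mu_shape, 0.2, None)
    mu = total_mu * mu_shape / mu_shape.sum()

    cps = []
    # aperture edges wander smoothly around a base field
    base_a = -field_half_width * np.ones(n_leaf_pairs)
    base_b = field_half_width * np.ones(n_leaf_pairs)
    phase_a = rng.uniform(0, 2 * np.pi, (3, n_leaf_pairs))
    phase_b = rng.uniform(0, 2 * np.pi, (3, n_leaf_pairs))
    cum = 0.0
    for i in range(n_cp):
        wobble_a = sum(modulation * field_half_width * 0.25 / k
                       * np.sin(k * t[i] + phase_a[k - 1]) for k in (1, 2, 3))
        wobble_b = sum(modulation * field_half_width * 0.25 / k
                       * np.sin(k * t[i] + phase_b[k - 1]) for k in (1, 2, 3))
        a = base_a + wobble_a
        b = base_b + wobble_b
        lo = np.minimum(a, b - 2.0)
        cum += mu[i]
        cps.append(ControlPoint(index=i, gantry_angle=float(angles[i] % 360.0),
                                leaf_a=lo, leaf_b=b, mu=float(mu[i]),
                                cumulative_mu=float(cum)))
    # snap terminal cumulative MU to the exact total
    last = cps[-1]
    cps[-1] = ControlPoint(last.index, last.gantry_angle, last.leaf_a,
                           last.leaf_b, last.mu + (total_mu - cum), total_mu)
    return DiscretizedArc(tuple(cps), "coarse", total_mu)


def _smooth_drift(n: int, amplitude: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Sum of <= 3 random-phase sinusoids over the arc, peak-clipped to the
    amplitude; zero-mean by construction of the harmonics."""
    if amplitude == 0:
        return np.zeros(n)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    drift = np.zeros(n)
    weights = rng.dirichlet(np.ones(3))
    for k, w in zip((1, 2, 3), weights):
        drift += w * np.sin(k * t + rng.uniform(0, 2 * np.pi))
    peak = np.max(np.abs(drift))
    if peak > 0:
        drift *= amplitude / peak
    return drift


def emulate_delivery(plan: DiscretizedArc, errors: ErrorModel | None = None,
                     seed: int = 0, records_per_cp: int = 1,
                     ) -> tuple[DeliveryLog, np.ndarray]:
    """Produce the delivery log of a plan plus the ground-truth weights x*.

    Records are written at the 0.25 s beam-on cadence, ``records_per_cp``
    per plan CP (machine state linearly interpolated inside a CP, leaf and
    gantry jitter injected per record).  The logged MU counter follows the
    plan — but the *delivered output* of CP i is ``x*_i`` times its logged
    MU, a smooth per-CP drift invisible to the log (the discretization and
    delivery error the film feedback exists to recover).  The drift is
    normalized so total delivered MU equals total logged MU (the counter is
    globally calibrated; errors redistribute output along the arc).  With a
    zero error model the log replays the plan exactly and x* = 1.
    """
    errors = errors or ErrorModel(0.0, 0.0, 0.0)
    rng = np.random.default_rng(seed)
    n = len(plan)
    drift = _smooth_drift(n, errors.mu_drift, rng)
    mu_plan = plan.mu_vector
    # conserve total delivered MU (the counter is globally calibrated):
    # center the drift under the MU weighting, then re-cap its amplitude
    drift -= (drift * mu_plan).sum() / mu_plan.sum()
    peak = np.max(np.abs(drift)) if n else 0.0
    if errors.mu_drift > 0 and peak > errors.mu_drift:
        drift *= errors.mu_drift / peak
    x_star = 1.0 + drift

    mu_actual = mu_plan.copy()          # what the counter records
    cadence = 0.25
    records = [LogRecord(time=0.0, gantry_angle=_start_angle(plan),
                         leaf_a=plan.control_points[0].leaf_a.copy(),
                         leaf_b=plan.control_points[0].leaf_b.copy(),
                         cumulative_mu=0.0, beam_on=True)]
    t = 0.0
    cum = 0.0
    for i, cp in enumerate(plan.control_points):
        prev = plan.control_points[i - 1] if i > 0 else cp
        for s in range(1, records_per_cp + 1):
            f = s / records_per_cp
            t += cadence
            cum_s = cum + f * mu_actual[i]
            ang = _lerp_angle(prev.gantry_angle if i > 0 else _start_angle(plan),
                              cp.gantry_angle, f)
            la = (1 - f) * prev.leaf_a + f * cp.leaf_a
            lb = (1 - f) * prev.leaf_b + f * cp.leaf_b
            if errors.leaf_jitter_mm > 0:
                la = la + rng.normal(0, errors.leaf_jitter_mm, la.shape)
                lb = lb + rng.normal(0, errors.leaf_jitter_mm, lb.shape)
                la = np.minimum(la, lb)
            if errors.angle_jitter_deg > 0:
                ang += rng.normal(0, errors.angle_jitter_deg)
            records.append(LogRecord(time=round(t, 6),
                                     gantry_angle=float(ang % 360.0),
                                     leaf_a=la, leaf_b=lb,
                                     cumulative_mu=float(cum_s),
                                     beam_on=True))
        cum += mu_actual[i]
    return DeliveryLog(tuple(records)), x_star


def _start_angle(plan: DiscretizedArc) -> float:
    first = plan.control_points[0].gantry_angle
    if len(plan) > 1:
        step = plan.control_points[1].gantry_angle - first
    else:
        step = 0.0
    return float((first - step) % 360.0)


def _lerp_angle(a: float, b: float, f: float) -> float:
    d = (b - a + 180.0) % 360.0 - 180.0
    return a + f * d


def default_calibration() -> CalibrationCurve:
    """The synthetic film batch's exact sensitometric curve."""
    return CalibrationCurve(params=dict(DEFAULT_RESPONSE),
                            dose_range=(0.0, 400.0))


def scroll_to_film_scan(scroll: ScrollImage, cal: CalibrationCurve,
                        noise_sd: float = 0.003,
                        lateral_falloff: float = 0.0,
                        seed: int = 0) -> FilmScan:
    """Forward film model: dose map -> RGB scan.

    Applies the sensitometric response per channel, an optional parabolic
    lateral scanner profile (``lateral_falloff`` fractional droop at the
    edges) and additive Gaussian scanner noise (SD as a fraction of signal).
    """
    rng = np.random.default_rng(seed)
    dose_cgy = scroll.values * 100.0
    w = scroll.values.shape[1]
    xs = np.linspace(-1.0, 1.0, w)
    profile = 1.0 - lateral_falloff * xs**2
    channels = {}
    for ch, p in cal.params.items():
        v = film_response(dose_cgy, *p) * profile[None, :]
        if noise_sd > 0:
            v = v + noise_sd * v * rng.standard_normal(v.shape)
        channels[ch] = np.clip(v, 0.0, 1.0)
    return FilmScan(channels)


@dataclass
class Scenario:
    """One reproducible end-to-end verification case."""

    seed: int
    plan: DiscretizedArc
    log: DeliveryLog
    arc: DiscretizedArc                 # coarse discretization of the log
    x_star: np.ndarray                  # ground-truth per-CP weights
    phantom: PhantomModel
    beam_model: BeamModel
    C: ContributionMatrix               # at the measurement points (noisy)
    C_clean: ContributionMatrix         # noiseless matrix, for evaluation
    d_true: np.ndarray                  # noiseless dose at the rows (Gy)
    d_meas: np.ndarray                  # measured dose (noise applied)
    measurement_points: np.ndarray
    row_provenance: np.ndarray
    chamber_true_gy: float
    outer_scroll_shape: tuple[int, int]
    inner_scroll_shape: tuple[int, int]


def _scroll_point_block(radius: float, z_lim: float, dtheta_deg: float,
                        z_step: float):
    thetas = np.radians(np.arange(0.0, 360.0, dtheta_deg))
    zs = np.arange(-z_lim, z_lim + z_step / 2, z_step)
    zz, tt = np.meshgrid(zs, thetas, indexing="ij")
    pts = np.column_stack([radius * np.sin(tt).ravel(),
                           radius * np.cos(tt).ravel(), zz.ravel()])
    return pts, (len(zs), len(thetas))


def make_scenario(seed: int = 0, n_cp: int = 48, setup: str = "small",
                  errors: ErrorModel | None = None, total_mu: float = 200.0,
                  modulation: float = 0.5, dtheta_deg: float = 1.0,
                  z_step: float = 5.0, z_lim: float = 60.0,
                  mc_noise: float = 0.0, film_noise: float = 0.0,
                  chamber_noise: float = 0.0) -> Scenario:
    """Build a full scenario: plan -> delivery log -> coarse arc ->
    contribution matrix at the scroll/chamber points -> true doses ->
    (optionally) noisy measurements.

    Measurement rows are the outer and inner scroll sample points (spacing
    set by ``dtheta_deg`` x ``z_step``) plus the chamber; noise levels are
    relative SDs applied to the matrix (Monte Carlo statistics emulation),
    the measurement doses (film) and the chamber reading.
    """
    rng = np.random.default_rng(seed)
    plan = make_arc_plan(n_cp=n_cp, total_mu=total_mu, modulation=modulation,
                         seed=seed)
    log, x_star = emulate_delivery(plan, errors or ErrorModel(), seed=seed + 1)
    arc = discretize(log, "coarse")
    if len(arc) != len(x_star):
        raise RuntimeError("coarse arc does not align with the plan CPs")

    phantom, _ = build_phantom(setup, voxel_size=(2.5, 2.5, 2.5), margin=5.0)
    medium = phantom.medium()
    model = BeamModel()

    outer_pts, outer_shape = _scroll_point_block(
        phantom.outer_scroll_radius, z_lim, dtheta_deg, z_step)
    inner_pts, inner_shape = _scroll_point_block(
        phantom.inner_scroll_radius, z_lim, dtheta_deg, z_step)
    pts = np.vstack([outer_pts, inner_pts,
                     np.asarray(phantom.chamber_point)[None, :]])
    prov = np.array(["outer"] * len(outer_pts) + ["inner"] * len(inner_pts)
                    + ["chamber"])

    C = build_contribution_matrix(arc, pts, model, medium, row_labels=prov)
    C_clean = C
    d_true = C.dose_for_weights(x_star)

    if mc_noise > 0:
        noisy = C.entries * (1.0 + mc_noise * rng.standard_normal(
            C.entries.shape))
        C = ContributionMatrix(entries=np.clip(noisy, 0.0, None),
                               row_points=C.row_points, cp_mu=C.cp_mu,
                               row_labels=C.row_labels)
    d_meas = d_true.copy()
    if film_noise > 0:
        d_meas[:-1] = d_meas[:-1] * (
            1.0 + film_noise * rng.standard_normal(len(d_meas) - 1))
    if chamber_noise > 0:
        d_meas[-1] = d_meas[-1] * (1.0 + chamber_noise * rng.standard_normal())
    d_meas = np.clip(d_meas, 0.0, None)

    return Scenario(seed=seed, plan=plan, log=log, arc=arc, x_star=x_star,
                    phantom=phantom, beam_model=model, C=C, C_clean=C_clean,
                    d_true=d_true, d_meas=d_meas, measurement_points=pts,
                    row_provenance=prov, chamber_true_gy=float(d_true[-1]),
                    outer_scroll_shape=outer_shape,
                    inner_scroll_shape=inner_shape)


def synthesize_measurements(scroll: ScrollImage, cal: CalibrationCurve,
                            noise_sd: float = 0.003,
                            lateral_falloff: float = 0.03,
                            shift_px: tuple[float, float] = (0.0, 0.0),
                            rotation_deg: float = 0.0,
                            seed: int = 0) -> FilmScan:
    """Full film forward model for a calculated scroll dose: response +
    lateral profile + scanner noise + a small rigid misregistration."""
    from .film import RigidTransform2D, apply_rigid

    scan = scroll_to_film_scan(scroll, cal, noise_sd=noise_sd,
                               lateral_falloff=lateral_falloff, seed=seed)
    if rotation_deg != 0.0 or any(s != 0 for s in shift_px):
        t = RigidTransform2D(shift_px, rotation_deg)
        scan = FilmScan({c: apply_rigid(v, t) for c, v in
                         scan.channels.items()},
                        resolution_dpi=scan.resolution_dpi)
    return scan
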