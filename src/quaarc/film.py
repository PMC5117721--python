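"""Radiochromic film dosimetry: calibration, multichannel dose conversion,
scanner lateral correction and rigid registration.

EBT-family film darkens with dose; a flatbed scan (48-bit RGB, 75 dpi here)
maps dose to a per-channel normalized pixel value.  The sensitometric
response is modeled with the rational form

    v_ch(D) = a_ch + b_ch / (D - c_ch),        D in cGy, b > 0, c < 0,

which is monotone decreasing on the calibrated range and has a well-
conditioned inverse.  A calibration batch of 16 film pieces irradiated from
0 to 400 cGy fixes (a, b, c) per channel by least squares.

Dose conversion uses the multichannel common-mode-disturbance model: each
pixel's three channel values are explained by one dose D and one scalar
disturbance Delta (film-thickness/scan artifacts that move all channels
together),

    minimize over (D, Delta):  sum_ch ( v_ch - vhat_ch(D) * (1 + Delta) )^2 .

Forcing Delta = 0 recovers plain single-channel (green) inversion.  The
scanner's lateral (cross-scan) response non-uniformity is corrected by a
per-column profile; the longitudinal effect is neglected as negligible.
Small rigid misalignments between film and calculation are recovered by an
exhaustive coarse-to-fine mutual-information search (deterministic — no
random restarts).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "CalibrationCurve",
    "FilmScan",
    "RigidTransform2D",
    "fit_calibration",
    "film_response",
    "multichannel_dose",
    "lateral_correction",
    "register_rigid_mi",
    "apply_rigid",
]

CHANNELS = ("red", "green", "blue")

# Default forward-model parameters (a, b, c) per channel, chosen to mimic an
# EBT3-like response normalized to [0, 1]: bright unexposed film, red most
# sensitive at low dose, blue least.
DEFAULT_RESPONSE = {
    "red": (0.085, 72.0, -85.0),
    "green": (0.180, 89.0, -120.0),
    "blue": (0.430, 78.0, -160.0),
}


def film_response(dose_cgy, a: float, b: float, c: float):
    """Rational sensitometric response v(D) = a + b/(D - c)."""
    return a + b / (np.asarray(dose_cgy, dtype=float) - c)


def _inverse_response(v, a: float, b: float, c: float):
    """Closed-form inverse D(v) = c + b/(v - a)."""
    return c + b / (np.asarray(v, dtype=float) - a)


@dataclass
class CalibrationCurve:
    """Fitted per-channel response over the calibrated dose range (cGy)."""

    params: dict[str, tuple[float, float, float]]   # channel -> (a, b, c)
    dose_range: tuple[float, float] = (0.0, 400.0)
    residual_rms: dict[str, float] = field(default_factory=dict)

    def response(self, channel: str, dose_cgy):
        return film_response(dose_cgy, *self.params[channel])

    def inverse(self, channel: str, value):
        return _inverse_response(value, *self.params[channel])

    def value_range(self, channel: str) -> tuple[float, float]:
        lo = float(self.response(channel, self.dose_range[1]))
        hi = float(self.response(channel, self.dose_range[0]))
        return (lo, hi)

    def to_json(self) -> str:
        return json.dumps({"params": {k: list(v) for k, v in self.params.items()},
                           "dose_range": list(self.dose_range),
                           "residual_rms": self.residual_rms}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(params={k: tuple(v) for k, v in d["params"].items()},
                   dose_range=tuple(d["dose_range"]),
                   residual_rms=d.get("residual_rms", {}))


@dataclass
class FilmScan:
    """A scanned film: one 2-D array per RGB channel, 16 bits per channel
    semantics (values stored normalized to [0, 1])."""

    channels: dict[str, np.ndarray]
    resolution_dpi: float = 75.0
    portrait: bool = True

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channel shapes differ")
        if self.resolution_dpi <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_mm(self) -> float:
        return 25.4 / self.resolution_dpi

    def to_uint16(self) -> np.ndarray:
        """(H, W, 3) 16-bit array in RGB order (for 48-bit TIFF export)."""
        out = np.stack([self.channels[c] for c in CHANNELS], axis=-1)
        return np.clip(np.round(out * 65535.0), 0, 65535).astype(np.uint16)

    @classmethod
    def from_uint16(cls, arr: np.ndarray, resolution_dpi: float = 75.0
                    ) -> "FilmScan":
        arr = np.asarray(arr)
        return cls({c: arr[..., i].astype(float) / 65535.0
                    for i, c in enumerate(CHANNELS)},
                   resolution_dpi=resolution_dpi)


def fit_calibration(doses_cgy, values: dict[str, np.ndarray],
                    dose_range: tuple[float, float] = (0.0, 400.0)
                    ) -> CalibrationCurve:
    """Least-squares fit of the rational response per channel.

    Requires at least 13 distinct dose points including 0.  A channel whose
    data are not monotone in dose is rejected with a warning and omitted
    from the returned curve.
    """
    doses = np.asarray(doses_cgy, dtype=float)
    if len(np.unique(doses)) < 13:
        raise ValueError("calibration needs at least 13 distinct dose points")
    if doses.min() > 1e-9:
        raise ValueError("calibration must include an unexposed (0 cGy) piece")
    order = np.argsort(doses)
    params, rms = {}, {}
    for ch, v in values.items():
        v = np.asarray(v, dtype=float)
        dv = np.diff(v[order])
        if not (np.all(dv <= 1e-12) or np.all(dv >= -1e-12)):
            warnings.warn(f"channel {ch}: non-monotone calibration data, "
                          "channel rejected")
            continue
        a0 = float(v[order][-1]) * 0.9
        c0 = -100.0
        b0 = float((v[order][0] - a0) * (0.0 - c0))
        try:
            popt, _ = optimize.curve_fit(film_response, doses, v,
                                         p0=(a0, b0, c0), maxfev=20000)
        except RuntimeError as exc:
            warnings.warn(f"channel {ch}: fit failed ({exc}), channel rejected")
            continue
        if popt[2] >= 0:
            warnings.warn(f"channel {ch}: fitted pole inside dose axis, "
                          "channel rejected")
            continue
        params[ch] = tuple(float(p) for p in popt)
        rms[ch] = float(np.sqrt(np.mean((film_response(doses, *popt) - v) ** 2)))
    if not params:
        raise ValueError("no channel produced a valid calibration fit")
    return CalibrationCurve(params=params, dose_range=dose_range,
                            residual_rms=rms)


def multichannel_dose(
    scan: FilmScan,
    cal: CalibrationCurve,
    allow_disturbance: bool = True,
    dose_step_cgy: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a scan to dose (cGy) with the common-mode disturbance model.

    Returns ``(dose_map, disturbance_map, valid_mask)``.  For each candidate
    dose D on a fine grid over the calibrated range, the optimal common-mode
    factor (1 + Delta) has the closed form sum(v*vhat)/sum(vhat^2); the best
    D per pixel is the grid argmin refined by one parabolic step.  With
    ``allow_disturbance=False`` the model reduces to single-channel (green
    when available) inversion.  Pixels outside the calibrated value range in
    every channel are flagged invalid.
    """
    chans = [c for c in CHANNELS if c in cal.params and c in scan.channels]
    if not chans:
        raise ValueError("no channel common to scan and calibration")
    v = np.stack([scan.channels[c] for c in chans])        # (C, H, W)
    flat = v.reshape(len(chans), -1)                       # (C, N)

    lo, hi = cal.dose_range
    grid = np.arange(lo, hi + dose_step_cgy / 2, dose_step_cgy)
    vhat = np.stack([cal.response(c, grid) for c in chans])  # (C, G)

    if not allow_disturbance:
        ch = "green" if "green" in chans else chans[0]
        dose = cal.inverse(ch, scan.channels[ch])
        delta = np.zeros_like(dose)
        valid = (dose >= lo - 1.0) & (dose <= hi + 1.0)
        return np.clip(dose, lo, hi), delta, valid

    # residual^2(D) = sum_c v_c^2 - (sum_c v_c vhat_c)^2 / sum_c vhat_c^2
    vv = np.einsum("cn,cn->n", flat, flat)                 # (N,)
    cross = flat.T @ vhat                                  # (N, G)
    norm = np.einsum("cg,cg->g", vhat, vhat)               # (G,)
    score = cross**2 / norm                                # maximize over G
    j = np.argmax(score, axis=1)

    # parabolic refinement on the score around the grid argmax
    jm = np.clip(j, 1, len(grid) - 2)
    s0 = score[np.arange(len(j)), jm - 1]
    s1 = score[np.arange(len(j)), jm]
    s2 = score[np.arange(len(j)), jm + 1]
    denom = s0 - 2 * s1 + s2
    shift = np.where(np.abs(denom) > 1e-30,
                     0.5 * (s0 - s2) / np.where(denom != 0, denom, 1.0), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    dose = grid[jm] + shift * dose_step_cgy
    dose = np.clip(dose, lo, hi)

    # disturbance at the refined dose
    vhat_d = np.stack([cal.response(c, dose) for c in chans])   # (C, N)
    gain = np.einsum("cn,cn->n", flat, vhat_d) / np.einsum(
        "cn,cn->n", vhat_d, vhat_d)
    delta = gain - 1.0
    resid = np.sqrt(np.maximum(vv - np.einsum("cn,cn->n", flat, vhat_d) ** 2
                               / np.einsum("cn,cn->n", vhat_d, vhat_d), 0.0))

    # validity: each channel value inside its calibrated range (+ margin)
    valid = np.ones(flat.shape[1], dtype=bool)
    for i, c in enumerate(chans):
        vlo, vhi = cal.value_range(c)
        m = 0.02 * (vhi - vlo)
        valid &= (flat[i] >= vlo - m) & (flat[i] <= vhi + m)

    shape = scan.shape
    return dose.reshape(shape), delta.reshape(shape), valid.reshape(shape)


def lateral_correction(scan: FilmScan, profile: np.ndarray) -> FilmScan:
    """Divide each column by its lateral response factor (all channels).

    ``profile`` has one strictly positive factor per scan column; the
    longitudinal direction is left untouched.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (scan.shape[1],):
        raise ValueError("profile length must equal scan width")
    if np.any(profile <= 0):
        raise ValueError("lateral correction factors must be positive")
    return FilmScan({c: v / profile[None, :] for c, v in scan.channels.items()},
                    resolution_dpi=scan.resolution_dpi, portrait=scan.portrait)


# ----------------------------------------------------------------------------
# Rigid mutual-information registration
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane shift (pixels, (row, col)) and rotation (deg, about the
    image center); applying it to the moving image aligns it to the fixed."""

    shift: tuple[float, float]
    rotation_deg: float


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    h, _, _ = np.histogram2d(a[mask].ravel(), b[mask].ravel(), bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def apply_rigid(image: np.ndarray, t: RigidTransform2D,
                order: int = 1) -> np.ndarray:
    """Rotate about the center then shift, bilinear, zero-filled borders."""
    out = image
    if t.rotation_deg != 0:
        out = ndimage.rotate(out, t.rotation_deg, reshape=False, order=order,
                             mode="constant", cval=0.0)
    if any(s != 0 for s in t.shift):
        out = ndimage.shift(out, t.shift, order=order, mode="constant",
                            cval=0.0)
    return out


def register_rigid_mi(
    moving: np.ndarray,
    fixed: np.ndarray,
    shift_bound_px: float = 9.0,
    rot_bound_deg: float = 3.0,
    bins: int = 64,
) -> RigidTransform2D:
    """Exhaustive coarse-to-fine mutual-information rigid registration.

    Coarse pass: integer-pixel shifts and 1-degree rotations across the
    bounds; fine pass: 0.25-px / 0.25-deg steps around the coarse optimum.
    Deterministic.  A warning is raised when the optimum lies on the search
    boundary (the true misalignment may exceed the bounds).
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a shape")

    def mi_of(t: RigidTransform2D) -> float:
        return _mutual_information(apply_rigid(moving, t), fixed, bins)

    best, best_mi = RigidTransform2D((0.0, 0.0), 0.0), -np.inf
    rots = np.arange(-rot_bound_deg, rot_bound_deg + 0.5, 1.0)
    shifts = np.arange(-shift_bound_px, shift_bound_px + 0.5, 1.0)
    for r in rots:
        rotated = apply_rigid(moving, RigidTransform2D((0.0, 0.0), float(r)))
        for sy in shifts:
            for sx in shifts:
                cand = ndimage.shift(rotated, (sy, sx), order=1,
                                     mode="constant", cval=0.0)
                mi = _mutual_information(cand, fixed, bins)
                if mi > best_mi:
                    best_mi = mi
                    best = RigidTransform2D((float(sy), float(sx)), float(r))

    # fine pass around the coarse optimum
    fy, fx = best.shift
    fr = best.rotation_deg
    for r in np.arange(fr - 1.0, fr + 1.0 + 1e-9, 0.25):
        if abs(r) > rot_bound_deg + 1e-9:
            continue
        rotated = apply_rigid(moving, RigidTransform2D((0.0, 0.0), float(r)))
        for sy in np.arange(fy - 1.0, fy + 1.0 + 1e-9, 0.25):
            for sx in np.arange(fx - 1.0, fx + 1.0 + 1e-9, 0.25):
                if max(abs(sy), abs(sx)) > shift_bound_px + 1e-9:
                    continue
                cand = ndimage.shift(rotated, (sy, sx), order=1,
                                     mode="constant", cval=0.0)
                mi = _mutual_information(cand, fixed, bins)
                if mi > best_mi:
                    best_mi = mi
                    best = RigidTransform2D((float(sy), float(sx)), float(r))

    if (max(abs(best.shift[0]), abs(best.shift[1])) >= shift_bound_px - 1e-9
            or abs(best.rotation_deg) >= rot_bound_deg - 1e-9):
        warnings.warn("registration optimum at the search boundary; "
                      "misalignment may exceed the configured bounds")
    return best
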