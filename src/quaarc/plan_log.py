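"""Delivery-log parsing, validation and control-point discretization.

A linac delivery log is a time-stamped record of the machine state during a
dynamic arc: gantry angle, MLC leaf positions and the cumulative monitor-unit
(MU) counter, sampled at a fixed cadence (0.25 s while the beam is on, 1 s
while it is off).  Dose calculation cannot consume the raw stream directly:
the arc is discretized into control points (CPs), each carrying the aperture
and gantry angle frozen at a sampling instant and the MU delivered since the
previous CP.

Two discretization levels are provided:

``coarse``
    one CP per log record in which the cumulative MU advanced; records where
    the counter did not move (beam-off, beam holds) contribute no CP.
``fine``
    a denser, *non-equispaced* sampling whose CP density per arc sector is
    proportional to the local ``|dMU/dgantry|`` — i.e. the dose rate drives
    where the extra CPs go.  CP boundaries are placed at equal increments of
    cumulative MU (inverse-transform sampling of the normalized MU density),
    with every coarse boundary kept as a floor, and machine state at interior
    boundaries linearly interpolated in time.

The log dialect is an open CSV format (see :func:`parse_delivery_log`); a
reader for DICOM-RT Plan control-point sequences is provided for convenience.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "LogRecord",
    "DeliveryLog",
    "ControlPoint",
    "DiscretizedArc",
    "DiscretizationParams",
    "LogParseError",
    "LogIntegrityError",
    "EmptyArcError",
    "parse_delivery_log",
    "write_log",
    "read_dicom_plan",
    "discretize",
    "angular_mu_distribution",
]

BEAM_ON_CADENCE_S = 0.25   # log sampling period while the beam is on
BEAM_OFF_CADENCE_S = 1.0   # sampling period while the beam is held off


class LogParseError(ValueError):
    """Malformed log stream (bad header, bad row); names the offending line."""


class LogIntegrityError(ValueError):
    """Well-formed log that violates a physical invariant (MU monotonicity,
    crossed leaves, non-increasing timestamps)."""


class EmptyArcError(ValueError):
    """Discretization requested for a log that delivered no MU."""


@dataclass(frozen=True)
class LogRecord:
    """One time-stamped machine-state sample.

    ``leaf_a``/``leaf_b`` are the two opposing MLC bank positions in mm at
    the isocenter plane, one entry per leaf pair; the aperture is open where
    ``leaf_a <= u <= leaf_b``.
    """

    time: float                 # s from delivery start
    gantry_angle: float         # deg, IEC 61217, [0, 360)
    leaf_a: np.ndarray          # mm, bank A (lower edge per pair)
    leaf_b: np.ndarray          # mm, bank B (upper edge per pair)
    cumulative_mu: float        # MU
    beam_on: bool

    def validate(self) -> None:
        if not 0.0 <= self.gantry_angle < 360.0:
            raise LogIntegrityError(
                f"gantry angle {self.gantry_angle} outside [0, 360) at t={self.time}"
            )
        if self.leaf_a.shape != self.leaf_b.shape:
            raise LogIntegrityError("leaf banks differ in length")
        if np.any(self.leaf_a > self.leaf_b + 1e-9):
            raise LogIntegrityError(f"crossed leaves at t={self.time}")
        if self.cumulative_mu < 0:
            raise LogIntegrityError(f"negative cumulative MU at t={self.time}")


@dataclass(frozen=True)
class DeliveryLog:
    """A validated, time-ordered delivery record."""

    records: tuple[LogRecord, ...]

    def __post_init__(self) -> None:
        times = np.array([r.time for r in self.records])
        if len(times) == 0:
            raise LogIntegrityError("empty log")
        if np.any(np.diff(times) <= 0):
            raise LogIntegrityError("timestamps not strictly increasing")
        mu = np.array([r.cumulative_mu for r in self.records])
        if np.any(np.diff(mu) < -1e-9):
            i = int(np.argmax(np.diff(mu) < -1e-9)) + 1
            raise LogIntegrityError(
                f"cumulative MU decreases at record {i} (t={times[i]})"
            )
        for r in self.records:
            r.validate()

    @property
    def total_mu(self) -> float:
        return float(self.records[-1].cumulative_mu)

    @property
    def arc_span(self) -> float:
        """Signed gantry travel in degrees (unwrapped across 0/360)."""
        ang = self.unwrapped_angles()
        return float(ang[-1] - ang[0])

    def unwrapped_angles(self) -> np.ndarray:
        ang = np.array([r.gantry_angle for r in self.records], dtype=float)
        return np.degrees(np.unwrap(np.radians(ang)))

    @property
    def n_leaf_pairs(self) -> int:
        return len(self.records[0].leaf_a)


@dataclass(frozen=True)
class ControlPoint:
    """A discrete delivery snapshot: aperture + angle + the MU attributed
    to the interval ending at this snapshot."""

    index: int
    gantry_angle: float         # deg (may exceed [0,360) after unwrapping)
    leaf_a: np.ndarray          # mm
    leaf_b: np.ndarray          # mm
    mu: float                   # MU delivered within this CP
    cumulative_mu: float        # MU at CP end


@dataclass(frozen=True)
class DiscretizedArc:
    control_points: tuple[ControlPoint, ...]
    level: Literal["coarse", "fine"]
    total_mu: float

    def __post_init__(self) -> None:
        mus = np.array([cp.mu for cp in self.control_points])
        if np.any(mus < -1e-12):
            raise LogIntegrityError("negative CP MU")
        if abs(mus.sum() - self.total_mu) > 1e-9:
            raise LogIntegrityError(
                f"MU not conserved: sum {mus.sum()} vs total {self.total_mu}"
            )

    @property
    def mu_vector(self) -> np.ndarray:
        return np.array([cp.mu for cp in self.control_points])

    @property
    def angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])

    def __len__(self) -> int:
        return len(self.control_points)


@dataclass(frozen=True)
class DiscretizationParams:
    """Knobs for :func:`discretize`.

    target_multiplier
        For the fine level: requested CP count as a multiple of the coarse
        count.  The delivered count tracks the request to within the
        granularity of the MU-quantile boundaries (typically a few %).
    """

    target_multiplier: float = 3.0


# ----------------------------------------------------------------------------
# CSV dialect
# ----------------------------------------------------------------------------
#
# Header: time_s,gantry_deg,mu_cum,beam_on,leaf_a_01..leaf_a_NN,leaf_b_01..leaf_b_NN
# One row per sample.  beam_on is 0/1.  Positions in mm at isocenter.

def _leaf_columns(n_pairs: int) -> tuple[list[str], list[str]]:
    a = [f"leaf_a_{i + 1:02d}" for i in range(n_pairs)]
    b = [f"leaf_b_{i + 1:02d}" for i in range(n_pairs)]
    return a, b


def parse_delivery_log(stream: TextIO | str) -> DeliveryLog:
    """Parse the CSV log dialect into a validated :class:`DeliveryLog`.

    Records are preserved verbatim — no resampling, no smoothing.  A
    malformed row raises :class:`LogParseError` naming the line; violated
    physical invariants raise :class:`LogIntegrityError`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        df = pd.read_csv(stream)
    except Exception as exc:  # pandas reports the line in its message
        raise LogParseError(f"malformed log CSV: {exc}") from exc

    required = {"time_s", "gantry_deg", "mu_cum", "beam_on"}
    if not required.issubset(df.columns):
        raise LogParseError(
            f"missing required columns {sorted(required - set(df.columns))}"
        )
    a_cols = sorted(c for c in df.columns if c.startswith("leaf_a_"))
    b_cols = sorted(c for c in df.columns if c.startswith("leaf_b_"))
    if len(a_cols) != len(b_cols) or not a_cols:
        raise LogParseError("leaf bank columns unbalanced or absent")
    if df[["time_s", "gantry_deg", "mu_cum"] + a_cols + b_cols].isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0]) + 2  # +header +1-based
        raise LogParseError(f"malformed row at line {bad}")

    records = tuple(
        LogRecord(
            time=float(df.at[i, "time_s"]),
            gantry_angle=float(df.at[i, "gantry_deg"]),
            leaf_a=df.loc[i, a_cols].to_numpy(dtype=float),
            leaf_b=df.loc[i, b_cols].to_numpy(dtype=float),
            cumulative_mu=float(df.at[i, "mu_cum"]),
            beam_on=bool(int(df.at[i, "beam_on"])),
        )
        for i in df.index
    )
    return DeliveryLog(records=records)


def write_log(log: DeliveryLog, stream: TextIO | None = None) -> str:
    """Serialize a log back to the CSV dialect (field-for-field round trip)."""
    n = log.n_leaf_pairs
    a_cols, b_cols = _leaf_columns(n)
    rows = []
    for r in log.records:
        row = {
            "time_s": r.time,
            "gantry_deg": r.gantry_angle,
            "mu_cum": r.cumulative_mu,
            "beam_on": int(r.beam_on),
        }
        row.update(dict(zip(a_cols, r.leaf_a)))
        row.update(dict(zip(b_cols, r.leaf_b)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["time_s", "gantry_deg", "mu_cum", "beam_on"]
                      + a_cols + b_cols)
    text = df.to_csv(index=False, float_format="%.6g")
    if stream is not None:
        stream.write(text)
    return text


def read_dicom_plan(path) -> DiscretizedArc:
    """Read the first beam of a DICOM-RT Plan into a coarse arc.

    Control-point gantry angles, MLC boundaries and cumulative meterset
    weights are mapped onto :class:`ControlPoint`; the CP MU is the meterset
    increment scaled by the beam meterset.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    beam = ds.BeamSequence[0]
    beam_mu = None
    for fg in ds.FractionGroupSequence[0].ReferencedBeamSequence:
        if int(fg.ReferencedBeamNumber) == int(beam.BeamNumber):
            beam_mu = float(fg.BeamMeterset)
    if beam_mu is None:
        raise ValueError("beam meterset not found in plan")

    cps = []
    prev_w = 0.0
    angle = 0.0
    leaf_a = leaf_b = None
    for i, cp in enumerate(beam.ControlPointSequence):
        if hasattr(cp, "GantryAngle"):
            angle = float(cp.GantryAngle)
        for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            if dev.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                pos = np.asarray(dev.LeafJawPositions, dtype=float)
                n = len(pos) // 2
                leaf_a, leaf_b = pos[:n], pos[n:]
        w = float(cp.CumulativeMetersetWeight)
        dmu = (w - prev_w) * beam_mu
        if dmu > 0:
            cps.append(
                ControlPoint(
                    index=len(cps),
                    gantry_angle=angle,
                    leaf_a=leaf_a.copy(),
                    leaf_b=leaf_b.copy(),
                    mu=dmu,
                    cumulative_mu=w * beam_mu,
                )
            )
        prev_w = w
    return DiscretizedArc(control_points=tuple(cps), level="coarse",
                          total_mu=beam_mu)


# ----------------------------------------------------------------------------
# Discretization
# ----------------------------------------------------------------------------

def discretize(
    log: DeliveryLog,
    level: Literal["coarse", "fine"] = "coarse",
    params: DiscretizationParams | None = None,
) -> DiscretizedArc:
    """Reduce a delivery log to a control-point sequence.

    Coarse: one CP per record whose cumulative MU advanced, carrying that
    record's gantry angle and leaf snapshot.  Fine: CP boundaries at equal
    cumulative-MU quanta (density proportional to the local dose rate per
    degree), the coarse boundaries retained as a floor, and machine state at
    interior boundaries interpolated linearly in time.  Both levels conserve
    total MU to 1e-9.
    """
    params = params or DiscretizationParams()
    if log.total_mu <= 0:
        raise EmptyArcError("log delivered no MU")

    times = np.array([r.time for r in log.records])
    mu = np.array([r.cumulative_mu for r in log.records])
    angles = log.unwrapped_angles()

    # coarse boundaries: indices of records where the counter advanced
    dmu = np.diff(mu)
    adv = np.nonzero(dmu > 0)[0] + 1  # record index ending each coarse CP

    if level == "coarse":
        cps = []
        prev_cum = mu[0]
        for k, i in enumerate(adv):
            r = log.records[i]
            cps.append(
                ControlPoint(
                    index=k,
                    gantry_angle=angles[i],
                    leaf_a=r.leaf_a.copy(),
                    leaf_b=r.leaf_b.copy(),
                    mu=float(mu[i] - prev_cum),
                    cumulative_mu=float(mu[i]),
                )
            )
            prev_cum = mu[i]
        return DiscretizedArc(tuple(cps), "coarse", log.total_mu)

    if level != "fine":
        raise ValueError(f"unknown level {level!r}")
    if params.target_multiplier < 1:
        raise ValueError("target_multiplier must be >= 1")

    n_coarse = len(adv)
    n_target = int(round(params.target_multiplier * n_coarse))

    # Inverse-transform sampling of the |dMU| density: each coarse interval
    # is split into max(1, round(target * dMU_i / total)) equal-MU sub-CPs —
    # the CP density per arc sector tracks the local dose rate, with one CP
    # per coarse CP as the floor.
    dmu_adv = np.empty(n_coarse)
    prev = mu[0]
    for k, i in enumerate(adv):
        dmu_adv[k] = mu[i] - prev
        prev = mu[i]
    n_sub = np.maximum(1, np.round(n_target * dmu_adv / dmu_adv.sum())
                       .astype(int))

    # boundary times: equal-MU quanta inside each coarse interval (MU is
    # linear in time between records, so quanta are linear in time too)
    t_bounds = []
    prev_i = 0
    prev_cum = mu[0]
    for k, i in enumerate(adv):
        t0, t1 = times[prev_i], times[i]
        seg_mu = np.linspace(prev_cum, mu[i], n_sub[k] + 1)[1:]
        # invert the piecewise-linear cumulative curve on [t0, t1]
        seg = slice(prev_i, i + 1)
        t_bounds.extend(np.interp(seg_mu, mu[seg], times[seg]))
        prev_i = i
        prev_cum = mu[i]
    t_bounds = np.asarray(t_bounds)

    leaf_a_all = np.stack([r.leaf_a for r in log.records])
    leaf_b_all = np.stack([r.leaf_b for r in log.records])

    cps = []
    prev_cum = mu[0]
    k = 0
    for t in t_bounds:
        cum = float(np.interp(t, times, mu))
        d = cum - prev_cum
        if d <= 1e-12:
            continue
        ang = float(np.interp(t, times, angles))
        la = np.array([np.interp(t, times, leaf_a_all[:, j])
                       for j in range(leaf_a_all.shape[1])])
        lb = np.array([np.interp(t, times, leaf_b_all[:, j])
                       for j in range(leaf_b_all.shape[1])])
        cps.append(ControlPoint(index=k, gantry_angle=ang, leaf_a=la,
                                leaf_b=lb, mu=d, cumulative_mu=cum))
        prev_cum = cum
        k += 1
    # force exact conservation of the terminal quantum against interp rounding
    deficit = log.total_mu - sum(cp.mu for cp in cps)
    if abs(deficit) > 0:
        last = cps[-1]
        cps[-1] = ControlPoint(last.index, last.gantry_angle, last.leaf_a,
                               last.leaf_b, last.mu + deficit, log.total_mu)
    return DiscretizedArc(tuple(cps), "fine", log.total_mu)


def angular_mu_distribution(
    arc: DiscretizedArc, bin_width: float = 10.0
) -> pd.DataFrame:
    """Bin CP MU by gantry angle.

    Returns a DataFrame with columns ``angle_lo``, ``angle_hi``, ``mu``;
    bins tile the arc span and the bin sums conserve total MU exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ang = arc.angles
    lo = np.floor((ang.min() - 1e-9) / bin_width) * bin_width
    hi = np.ceil((ang.max() - 1e-9) / bin_width) * bin_width
    hi = max(hi, lo + bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    # right-closed bins: a CP sitting exactly on an edge belongs below it
    idx = np.clip(np.digitize(ang, edges, right=True) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=arc.mu_vector, minlength=len(edges) - 1)
    return pd.DataFrame(
        {"angle_lo": edges[:-1], "angle_hi": edges[1:], "mu": sums}
    )
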