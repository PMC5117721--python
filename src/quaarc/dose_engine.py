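"""Per-control-point dose computation and the linear contribution matrix.

The verification model needs, for every control point (CP) of a discretized
arc, the dose per monitor unit it deposits at every measurement location —
film-scroll pixels, the ionization-chamber point, patient-grid voxels.  Those
per-CP doses stacked column-wise form the contribution matrix ``C`` of the
constrained least-squares MU adjustment: total dose for MU weights ``x`` is
``C @ (x * mu_log)``, so everything downstream is linear algebra.

The engine here is a deterministic divergent-beam pencil model, not a
radiation-transport code: the beam diverges from a point source at the
gantry's source-axis distance, the MLC aperture is projected onto the
isocenter plane with an error-function penumbra of configurable width,
closed-leaf regions transmit a configurable fraction, and intensity falls
off as the exponential of the radiological depth accumulated along the ray.
That preserves every property the MU adjustment relies on — linearity,
superposition, rotational equivariance, monotone attenuation — while staying
desk-scale.  Externally computed per-CP dose grids (e.g. real Monte Carlo
output) can be loaded instead via :func:`load_cp_doses`; the rest of the
pipeline only sees the matrix.

Geometry convention: grid axes (x, y, z) with z along the phantom/patient
axis; the gantry rotates in the x–y plane; at gantry angle 0 the source sits
on +y, at 90 on +x (IEC 61217 viewed from the table).  MLC leaves are paired
along z, travel along the in-plane transverse direction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .plan_log import ControlPoint, DiscretizedArc

__all__ = [
    "DoseGrid",
    "BeamModel",
    "Medium",
    "GridMedium",
    "CylinderMedium",
    "ContributionMatrix",
    "cp_dose",
    "cp_dose_at_points",
    "build_contribution_matrix",
    "add_statistical_noise",
    "save_cp_doses",
    "load_cp_doses",
]


@dataclass
class DoseGrid:
    """A regular 3-D scalar field (dose in Gy, or Gy/MU when ``per_mu``).

    ``values`` is indexed ``[ix, iy, iz]``; the world position of voxel
    center ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size`` (mm).
    """

    origin: np.ndarray                  # mm, (3,)
    voxel_size: np.ndarray              # mm, (3,), default 1.25 x 1.25 x 1
    values: np.ndarray                  # Gy (or Gy/MU), shape (nx, ny, nz)
    per_mu: bool = False

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")

    @classmethod
    def empty(cls, origin, voxel_size, shape, per_mu=False) -> "DoseGrid":
        return cls(np.asarray(origin, float), np.asarray(voxel_size, float),
                   np.zeros(shape, dtype=float), per_mu)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (N, 3) to fractional voxel indices."""
        return (np.atleast_2d(points) - self.origin) / self.voxel_size

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (N, 3), C-order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + idx * self.voxel_size

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Trilinear (order=1) interpolation at world points; 0 outside."""
        ci = self.world_to_index(points).T
        return ndimage.map_coordinates(self.values, ci, order=order,
                                       mode="constant", cval=0.0)

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.origin.copy(), self.voxel_size.copy(),
                        self.values.copy(), self.per_mu)


@dataclass(frozen=True)
class BeamModel:
    """Parameters of the simplified divergent-beam engine.

    source_distance : mm — source-to-isocenter distance (SAD).
    kernel_sigma : mm — Gaussian penumbra width at isocenter.
    mu_to_gy : Gy/MU — open-beam dose per MU at zero radiological depth.
    attenuation_coeff : 1/mm — effective linear attenuation per mm of
        unit-density (water-equivalent) path.
    leaf_transmission : fraction transmitted through closed leaves.
    """

    source_distance: float = 1000.0
    kernel_sigma: float = 3.0
    mu_to_gy: float = 0.02
    attenuation_coeff: float = 0.005
    leaf_transmission: float = 0.015
    leaf_z_min: float = -100.0          # mm, extent of the leaf array along z
    leaf_z_max: float = 100.0
    depth_step: float = 2.0             # mm, ray-marching step for grid media

    def __post_init__(self) -> None:
        if min(self.source_distance, self.kernel_sigma, self.mu_to_gy,
               self.attenuation_coeff) <= 0:
            raise ValueError("beam model parameters must be positive")
        if not 0 <= self.leaf_transmission < 1:
            raise ValueError("leaf_transmission must be in [0, 1)")


# ----------------------------------------------------------------------------
# Media: where radiological depth comes from
# ----------------------------------------------------------------------------

class Medium:
    """Interface: radiological depth (mm water-equivalent) from the source to
    each query point."""

    def radiological_depth(self, points: np.ndarray, source: np.ndarray,
                           model: BeamModel) -> np.ndarray:
        raise NotImplementedError


@dataclass
class GridMedium(Medium):
    """Density sampled on a :class:`DoseGrid` (g/cm^3); depth accumulated by
    midpoint ray-marching from each point back toward the source."""

    density: DoseGrid
    max_path: float | None = None       # mm marched back from the point

    def radiological_depth(self, points, source, model):
        points = np.atleast_2d(points).astype(float)
        if self.max_path is None:
            extent = self.density.voxel_size * np.array(self.density.shape)
            self.max_path = float(np.linalg.norm(extent)) + 10.0
        step = model.depth_step
        n = int(np.ceil(self.max_path / step))
        back = source - points
        back /= np.linalg.norm(back, axis=1, keepdims=True)
        # midpoint samples: points + back * (k + 0.5) * step
        ks = (np.arange(n) + 0.5) * step
        samples = points[:, None, :] + back[:, None, :] * ks[None, :, None]
        rho = self.density.sample(samples.reshape(-1, 3)).reshape(len(points), n)
        return rho.sum(axis=1) * step


@dataclass(frozen=True)
class CylinderMedium(Medium):
    """Homogeneous cylinder (axis along z): chord length from entry to the
    point, in closed form.  Exact — no marching error; the natural medium for
    the PMMA verification phantom."""

    center: tuple[float, float] = (0.0, 0.0)    # mm, cylinder axis in x-y
    radius: float = 100.0                       # mm
    z_min: float = -140.0
    z_max: float = 140.0
    density: float = 1.19                       # g/cm^3 (PMMA)

    def radiological_depth(self, points, source, model):
        p = np.atleast_2d(points).astype(float)
        c = np.array([*self.center, 0.0])
        # ray p + t*(source - p), t in [0, 1]; intersect infinite cylinder
        d = source - p
        px, py = p[:, 0] - c[0], p[:, 1] - c[1]
        dx, dy = d[:, 0], d[:, 1]
        a = dx**2 + dy**2
        b = 2 * (px * dx + py * dy)
        cc = px**2 + py**2 - self.radius**2
        disc = b**2 - 4 * a * cc
        ok = (disc > 0) & (a > 0)
        sq = np.sqrt(np.maximum(disc, 0.0))
        denom = np.where(a > 0, 2 * a, 1.0)
        t1 = (-b - sq) / denom
        t2 = (-b + sq) / denom
        t_lo = np.minimum(t1, t2)
        t_hi = np.maximum(t1, t2)
        # intersect with the z slab of the finite cylinder
        dz = d[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            tz1 = np.where(dz != 0, (self.z_min - p[:, 2]) / dz,
                           np.where((p[:, 2] >= self.z_min), -np.inf, np.inf))
            tz2 = np.where(dz != 0, (self.z_max - p[:, 2]) / dz,
                           np.where((p[:, 2] <= self.z_max), np.inf, -np.inf))
        t_lo = np.maximum(t_lo, np.minimum(tz1, tz2))
        t_hi = np.minimum(t_hi, np.maximum(tz1, tz2))
        # keep the part of the segment between the point (t=0) and the source (t=1)
        seg = np.maximum(np.minimum(t_hi, 1.0) - np.maximum(t_lo, 0.0), 0.0)
        length = seg * np.linalg.norm(d, axis=1)
        return np.where(ok, length * self.density, 0.0)


# ----------------------------------------------------------------------------
# Beam geometry and per-CP dose
# ----------------------------------------------------------------------------

def _beam_frame(gantry_deg: float, sad: float):
    """Source position and (beam-axis e, cross-plane u, leaf-travel-normal v)
    unit vectors for a gantry angle."""
    th = np.radians(gantry_deg)
    src = np.array([sad * np.sin(th), sad * np.cos(th), 0.0])
    e = -src / sad                        # unit, toward isocenter
    u = np.array([np.cos(th), -np.sin(th), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    return src, e, u, v


def _aperture_transmission(u: np.ndarray, v: np.ndarray, cp: ControlPoint,
                           model: BeamModel) -> np.ndarray:
    """Smooth transmission of the MLC aperture at isocenter-plane coordinates
    (u across leaves, v along the leaf stack)."""
    n_pairs = len(cp.leaf_a)
    width = (model.leaf_z_max - model.leaf_z_min) / n_pairs
    pair = np.clip(((v - model.leaf_z_min) // width).astype(int), 0, n_pairs - 1)
    a = cp.leaf_a[pair]
    b = cp.leaf_b[pair]
    s = model.kernel_sigma
    f_u = ndtr((u - a) / s) - ndtr((u - b) / s)
    f_v = ndtr((v - model.leaf_z_min) / s) - ndtr((v - model.leaf_z_max) / s)
    lt = model.leaf_transmission
    return lt + (1.0 - lt) * f_u * f_v


def cp_dose_at_points(points: np.ndarray, cp: ControlPoint, model: BeamModel,
                      medium: Medium | None = None) -> np.ndarray:
    """Dose per MU (Gy/MU) of one control point at arbitrary world points.

    dose = mu_to_gy * T(u, v) * exp(-mu_eff * radiological_depth), with
    (u, v) the divergent projection of the point onto the isocenter plane.
    Rotating the gantry rotates the pattern exactly (the frame co-rotates).
    """
    points = np.atleast_2d(points).astype(float)
    src, e, uhat, vhat = _beam_frame(cp.gantry_angle, model.source_distance)
    rel = points - src
    w = rel @ e                                   # distance along beam axis
    w = np.maximum(w, 1e-6)
    scale = model.source_distance / w             # divergent back-projection
    u = (rel @ uhat) * scale
    v = (rel @ vhat) * scale
    t = _aperture_transmission(u, v, cp, model)
    if medium is not None:
        depth = medium.radiological_depth(points, src, model)
        t = t * np.exp(-model.attenuation_coeff * depth)
    return model.mu_to_gy * t


def cp_dose(grid: DoseGrid, cp: ControlPoint, model: BeamModel,
            medium: Medium | None = None) -> DoseGrid:
    """Per-MU dose of one control point evaluated on a full grid."""
    pts = grid.voxel_centers()
    vals = cp_dose_at_points(pts, cp, model, medium).reshape(grid.shape)
    return DoseGrid(grid.origin.copy(), grid.voxel_size.copy(), vals,
                    per_mu=True)


# ----------------------------------------------------------------------------
# Contribution matrix
# ----------------------------------------------------------------------------

@dataclass
class ContributionMatrix:
    """Per-CP dose per unit MU at sampled locations.

    ``entries[i, j]`` is Gy/MU of CP ``j`` at row point ``i``; the total dose
    for per-CP MU vector ``m`` is ``entries @ m``.
    """

    entries: np.ndarray                  # (n_rows, n_cps), Gy/MU, >= 0
    row_points: np.ndarray               # (n_rows, 3) world mm
    cp_mu: np.ndarray                    # (n_cps,) log-file MU per CP
    row_labels: np.ndarray | None = None  # provenance per row

    def __post_init__(self) -> None:
        if self.entries.ndim != 2:
            raise ValueError("entries must be 2-D")
        if len(self.cp_mu) != self.entries.shape[1]:
            raise ValueError("cp_mu length must match column count")
        if np.any(self.entries < -1e-15):
            raise ValueError("negative contribution entries")

    @property
    def n_rows(self) -> int:
        return self.entries.shape[0]

    @property
    def n_cps(self) -> int:
        return self.entries.shape[1]

    def dose_for_weights(self, x: np.ndarray) -> np.ndarray:
        """Total dose at the row points for MU weight vector x (1 = log)."""
        return self.entries @ (np.asarray(x) * self.cp_mu)


def build_contribution_matrix(
    arc: DiscretizedArc,
    points: np.ndarray,
    model: BeamModel,
    medium: Medium | None = None,
    row_labels: np.ndarray | None = None,
) -> ContributionMatrix:
    """Assemble C: column j = per-MU dose of CP j at the sample points."""
    points = np.atleast_2d(points).astype(float)
    if len(points) == 0:
        raise ValueError("empty sample point set")
    if len(arc) == 0:
        raise ValueError("empty arc")
    cols = np.empty((len(points), len(arc)))
    for j, cp in enumerate(arc.control_points):
        cols[:, j] = cp_dose_at_points(points, cp, model, medium)
    return ContributionMatrix(entries=cols, row_points=points,
                              cp_mu=arc.mu_vector, row_labels=row_labels)


def add_statistical_noise(dose: DoseGrid, rel_sigma: float,
                          seed: int) -> DoseGrid:
    """Emulate Monte Carlo statistical noise: independent zero-mean Gaussian
    perturbation with SD ``rel_sigma`` x local dose, clipped at zero.
    Bit-reproducible for a fixed seed."""
    if not 0 <= rel_sigma < 0.1:
        raise ValueError("rel_sigma must be in [0, 0.1)")
    if rel_sigma == 0:
        return dose.copy()
    rng = np.random.default_rng(seed)
    noisy = dose.values * (1.0 + rel_sigma * rng.standard_normal(dose.shape))
    return DoseGrid(dose.origin.copy(), dose.voxel_size.copy(),
                    np.clip(noisy, 0.0, None), dose.per_mu)


# ----------------------------------------------------------------------------
# Per-CP dose import/export (raw float32 + JSON header, one pair per CP)
# ----------------------------------------------------------------------------

def save_cp_doses(dirname: str, grids: Sequence[DoseGrid]) -> None:
    os.makedirs(dirname, exist_ok=True)
    for j, g in enumerate(grids):
        stem = os.path.join(dirname, f"cp_{j:04d}")
        header = {
            "origin": g.origin.tolist(),
            "voxel_size": g.voxel_size.tolist(),
            "shape": list(g.shape),
            "per_mu": g.per_mu,
            "dtype": "float32",
        }
        with open(stem + ".json", "w") as fh:
            json.dump(header, fh)
        g.values.astype(np.float32).tofile(stem + ".raw")


def load_cp_doses(dirname: str) -> list[DoseGrid]:
    grids = []
    names = sorted(n[:-5] for n in os.listdir(dirname) if n.endswith(".json"))
    for stem in names:
        with open(os.path.join(dirname, stem + ".json")) as fh:
            h = json.load(fh)
        vals = np.fromfile(os.path.join(dirname, stem + ".raw"),
                           dtype=np.float32).reshape(h["shape"]).astype(float)
        grids.append(DoseGrid(np.array(h["origin"]), np.array(h["voxel_size"]),
                              vals, h["per_mu"]))
    return grids
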