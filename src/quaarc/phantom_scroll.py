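"""Cylindrical verification phantom and unrolled film-scroll extraction.

The phantom is a pair of concentric PMMA cylinders (density 1.19 g/cm^3)
that hosts radiochromic film rolled at two radial distances: an outer scroll
at 1 cm depth, close to the beam entrance (a fluence estimate for every arc
angle), and an inner scroll at 6 cm depth (relative dose close to the
treatment region).  Two setups exist: *big* (30 cm diameter x 30 cm length)
and *small* (20 cm diameter x 28 cm length).  An ionization chamber sits at
the isocenter for absolute dose.

A rolled film, once scanned flat, is a planar z-vs-azimuth dose map; to
compare calculation with film, the calculated 3-D dose grid is "unrolled"
the same way: the cylinder surface of the film's radius is sampled every
0.5 degrees by trilinear interpolation among the neighboring voxels, giving
a :class:`ScrollImage` whose pixel width is radius x dtheta (0.7854 mm for
the 90-mm outer scroll at 0.5 degrees).  To absorb the residual mismatch
between the calculation and measurement coordinate systems, the extraction
is repeated with the isocenter shifted by +/-1 in-plane voxel along each
transverse axis and the five images combined (mean, with min/max envelopes
retained); the declared positional uncertainty is the voxel pitch,
+/-1.25 mm on the default grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .dose_engine import CylinderMedium, DoseGrid

__all__ = [
    "PMMA_DENSITY",
    "PhantomModel",
    "ScrollImage",
    "build_phantom",
    "extract_scroll",
    "scroll_ensemble",
]

PMMA_DENSITY = 1.19          # g/cm^3
OUTER_DEPTH_MM = 10.0        # film depth below the phantom surface
INNER_DEPTH_MM = 60.0

_SETUPS = {
    "big": {"diameter": 300.0, "length": 300.0},
    "small": {"diameter": 200.0, "length": 280.0},
}


@dataclass(frozen=True)
class PhantomModel:
    """Geometry of one phantom setup; distances in mm, density g/cm^3."""

    setup: Literal["big", "small"]
    diameter: float
    length: float
    density: float = PMMA_DENSITY
    chamber_point: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def outer_scroll_radius(self) -> float:
        return self.radius - OUTER_DEPTH_MM

    @property
    def inner_scroll_radius(self) -> float:
        return self.radius - INNER_DEPTH_MM

    @property
    def scroll_specs(self) -> list[dict]:
        return [
            {"label": "outer", "radius": self.outer_scroll_radius,
             "depth": OUTER_DEPTH_MM},
            {"label": "inner", "radius": self.inner_scroll_radius,
             "depth": INNER_DEPTH_MM},
        ]

    def medium(self) -> CylinderMedium:
        """Closed-form homogeneous-cylinder medium for the dose engine."""
        return CylinderMedium(center=(0.0, 0.0), radius=self.radius,
                              z_min=-self.length / 2, z_max=self.length / 2,
                              density=self.density)

    def to_json(self) -> str:
        return json.dumps({
            "setup": self.setup, "diameter": self.diameter,
            "length": self.length, "density": self.density,
            "chamber_point": list(self.chamber_point),
            "scrolls": self.scroll_specs,
        }, indent=2)


def build_phantom(
    setup: Literal["big", "small"] = "small",
    voxel_size: tuple[float, float, float] = (1.25, 1.25, 1.0),
    margin: float = 10.0,
) -> tuple[PhantomModel, DoseGrid]:
    """Phantom model plus a voxelized density grid centered on the isocenter.

    Voxels whose centers fall inside the cylinder carry PMMA density; the
    rest carry air (~0).  The grid extends ``margin`` mm beyond the cylinder.
    """
    spec = _SETUPS[setup]
    model = PhantomModel(setup=setup, **spec)
    vs = np.asarray(voxel_size, dtype=float)
    half = np.array([model.radius + margin, model.radius + margin,
                     model.length / 2 + margin])
    shape = np.ceil(2 * half / vs).astype(int)
    origin = -(shape - 1) * vs / 2.0       # voxel centers symmetric about 0
    grid = DoseGrid.empty(origin, vs, tuple(shape))
    idx = np.indices(grid.shape)
    x = origin[0] + idx[0] * vs[0]
    y = origin[1] + idx[1] * vs[1]
    z = origin[2] + idx[2] * vs[2]
    inside = (x**2 + y**2 <= model.radius**2) & (np.abs(z) <= model.length / 2)
    density = np.where(inside, model.density, 1.2e-3)   # air elsewhere
    grid.values = density
    return model, grid


@dataclass
class ScrollImage:
    """An unrolled cylindrical dose map: axis 0 = z, axis 1 = azimuth."""

    radius: float                 # mm
    dtheta: float                 # deg between azimuth samples
    theta_start: float            # deg of column 0
    z_start: float                # mm of row 0
    z_spacing: float              # mm between rows
    values: np.ndarray            # Gy, (n_z, n_theta)
    envelope_min: np.ndarray | None = None
    envelope_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("scroll values must be 2-D")
        if np.any(self.values < -1e-12):
            raise ValueError("negative scroll dose")

    @property
    def pixel_width(self) -> float:
        """Azimuthal pixel width in mm: radius x dtheta in radians."""
        return self.radius * np.radians(self.dtheta)

    @property
    def thetas(self) -> np.ndarray:
        return self.theta_start + self.dtheta * np.arange(self.values.shape[1])

    @property
    def zs(self) -> np.ndarray:
        return self.z_start + self.z_spacing * np.arange(self.values.shape[0])

    def sample_points(self) -> np.ndarray:
        """World coordinates (N, 3) of every scroll pixel, C-order (z fast
        varying last over theta)."""
        th = np.radians(self.thetas)
        zz, tt = np.meshgrid(self.zs, th, indexing="ij")
        x = self.radius * np.sin(tt)
        y = self.radius * np.cos(tt)
        return np.column_stack([x.ravel(), y.ravel(), zz.ravel()])


def _scroll_grid_points(radius, z_range, dtheta, z_spacing, theta_span,
                        theta_start):
    n_theta = int(round(theta_span / dtheta))
    thetas = theta_start + dtheta * np.arange(n_theta)
    zs = np.arange(z_range[0], z_range[1] + z_spacing / 2, z_spacing)
    th = np.radians(thetas)
    zz, tt = np.meshgrid(zs, th, indexing="ij")
    x = radius * np.sin(tt)
    y = radius * np.cos(tt)
    pts = np.column_stack([x.ravel(), y.ravel(), zz.ravel()])
    return pts, zs, n_theta


def extract_scroll(
    grid: DoseGrid,
    radius: float,
    z_range: tuple[float, float],
    dtheta: float = 0.5,
    theta_span: float = 360.0,
    theta_start: float = 0.0,
    z_spacing: float | None = None,
    order: int = 1,
    offset: tuple[float, float] = (0.0, 0.0),
) -> ScrollImage:
    """Unroll the dose on a cylinder surface from a 3-D grid.

    The value at (z, theta) is the trilinear interpolation of the grid at
    (r sin(theta) + ox, r cos(theta) + oy, z); theta = 0 points toward the
    gantry-zero entrance (+y), increasing clockwise seen from the gantry.
    ``order=0`` switches to nearest-neighbor sampling.  ``offset`` shifts the
    sampling isocenter in-plane (used by the ensemble).
    """
    if z_spacing is None:
        z_spacing = float(grid.voxel_size[2])
    # geometric guard: the cylinder must be inside the grid footprint
    gmin = grid.origin[:2]
    gmax = grid.origin[:2] + (np.array(grid.shape[:2]) - 1) * grid.voxel_size[:2]
    if (radius + abs(offset[0]) > min(-gmin[0], gmax[0]) + 1e-6 or
            radius + abs(offset[1]) > min(-gmin[1], gmax[1]) + 1e-6):
        raise ValueError(f"scroll radius {radius} mm outside the dose grid")
    pts, zs, n_theta = _scroll_grid_points(radius, z_range, dtheta,
                                           z_spacing, theta_span, theta_start)
    pts = pts + np.array([offset[0], offset[1], 0.0])
    vals = grid.sample(pts, order=order).reshape(len(zs), n_theta)
    return ScrollImage(radius=radius, dtheta=dtheta, theta_start=theta_start,
                       z_start=float(zs[0]), z_spacing=z_spacing,
                       values=np.clip(vals, 0.0, None))


def scroll_ensemble(
    grid: DoseGrid,
    radius: float,
    z_range: tuple[float, float],
    dtheta: float = 0.5,
    **kw,
) -> ScrollImage:
    """Mean of five scroll extractions: unshifted plus the isocenter shifted
    by +/-1 in-plane voxel along each transverse axis.

    The min/max over the five images is retained as an uncertainty envelope;
    the positional uncertainty this absorbs is one voxel pitch (+/-1.25 mm
    on the default grid).
    """
    dx, dy = float(grid.voxel_size[0]), float(grid.voxel_size[1])
    offsets = [(0.0, 0.0), (dx, 0.0), (-dx, 0.0), (0.0, dy), (0.0, -dy)]
    scrolls = [extract_scroll(grid, radius, z_range, dtheta, offset=o, **kw)
               for o in offsets]
    stack = np.stack([s.values for s in scrolls])
    base = scrolls[0]
    return ScrollImage(radius=base.radius, dtheta=base.dtheta,
                       theta_start=base.theta_start, z_start=base.z_start,
                       z_spacing=base.z_spacing, values=stack.mean(axis=0),
                       envelope_min=stack.min(axis=0),
                       envelope_max=stack.max(axis=0))
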