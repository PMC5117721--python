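"""Patient-dose reconstruction, DVH computation and absolute point dose.

After the MU adjustment, the per-CP patient dose contributions are
reweighted with the adjusted weights to give the experimentally
reconstructed 3-D dose on the patient grid; cumulative dose-volume
histograms (DVHs) per structure are the headline verification metric, and
the isocenter point dose is checked against the chamber reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dose_engine import ContributionMatrix, DoseGrid

__all__ = [
    "StructureMask",
    "DVHCurve",
    "reconstruct_dose",
    "compute_dvh",
    "point_dose_check",
    "make_cylindrical_structures",
]


@dataclass
class StructureMask:
    """A named boolean region on the patient grid (voxel-center inclusion)."""

    name: str
    mask: np.ndarray                    # bool, patient-grid shape
    voxel_volume_cm3: float

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError(f"structure {self.name!r} is empty")

    @property
    def volume_cm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_cm3


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure volume receiving at least
    each dose level.  Monotone non-increasing; 100 % at zero dose."""

    name: str
    bin_edges_gy: np.ndarray            # (n_bins + 1,)
    volume_pct: np.ndarray              # (n_bins + 1,), V(dose >= edge)

    def v_at(self, dose_gy: float) -> float:
        """Volume % receiving at least ``dose_gy`` (interpolated)."""
        return float(np.interp(dose_gy, self.bin_edges_gy, self.volume_pct))

    def d_at(self, volume_pct: float) -> float:
        """Minimum dose received by the hottest ``volume_pct`` % (e.g. D95)."""
        v = self.volume_pct
        return float(np.interp(-volume_pct, -v, self.bin_edges_gy))

    @property
    def d95(self) -> float:
        return self.d_at(95.0)

    @property
    def d2(self) -> float:
        return self.d_at(2.0)

    def to_csv(self) -> str:
        lines = ["dose_gy,volume_pct"]
        lines += [f"{d:.5g},{v:.5g}"
                  for d, v in zip(self.bin_edges_gy, self.volume_pct)]
        return "\n".join(lines) + "\n"


def reconstruct_dose(C_patient: ContributionMatrix, x: np.ndarray,
                     grid_template: DoseGrid | None = None) -> np.ndarray:
    """Dose at the patient rows for weight vector x: C_patient @ (x * mu_log).

    Returns the flat dose vector over the matrix rows; pass a grid template
    whose voxel count matches the rows to get a reshaped 3-D array instead.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != C_patient.n_cps:
        raise ValueError("weight vector length does not match CP count")
    dose = C_patient.dose_for_weights(x)
    if grid_template is not None:
        if int(np.prod(grid_template.shape)) != C_patient.n_rows:
            raise ValueError("grid template does not match matrix rows")
        return dose.reshape(grid_template.shape)
    return dose


def compute_dvh(dose: np.ndarray, mask: StructureMask,
                bin_width_gy: float = 0.01) -> DVHCurve:
    """Cumulative DVH by voxel counting with ``bin_width_gy`` bins."""
    if dose.shape != mask.mask.shape:
        raise ValueError("dose and mask shapes differ")
    vals = np.asarray(dose, dtype=float)[mask.mask]
    dmax = float(vals.max())
    edges = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    # V(edge) = % voxels with dose >= edge
    counts = np.array([(vals >= e).sum() for e in edges]) if len(edges) < 64 \
        else (len(vals) - np.searchsorted(np.sort(vals), edges, side="left"))
    vol = 100.0 * counts / len(vals)
    return DVHCurve(name=mask.name, bin_edges_gy=edges, volume_pct=vol)


def point_dose_check(dose_gy: float | DoseGrid, chamber_gy: float,
                     point=None) -> float:
    """Percent deviation of the calculated dose from the chamber reading:
    100 * (dose(point) - chamber) / chamber.

    Accepts either the already-interpolated dose value at the chamber point
    or a dose grid plus the point (trilinear interpolation).
    """
    if chamber_gy <= 0:
        raise ValueError("chamber dose must be positive")
    if isinstance(dose_gy, DoseGrid):
        if point is None:
            raise ValueError("a point is required with a dose grid")
        dose_val = float(dose_gy.sample(np.atleast_2d(point))[0])
    else:
        dose_val = float(dose_gy)
    return 100.0 * (dose_val - chamber_gy) / chamber_gy


def make_cylindrical_structures(grid: DoseGrid, ptv_radius: float = 30.0,
                                ptv_half_length: float = 30.0,
                                oar_gap: float = 5.0,
                                oar_thickness: float = 15.0
                                ) -> dict[str, StructureMask]:
    """Synthetic patient structures on a grid: a cylindrical PTV about the
    isocenter and a surrounding OAR shell.  Desk-scale stand-in for clinical
    structure sets."""
    idx = np.indices(grid.shape)
    x = grid.origin[0] + idx[0] * grid.voxel_size[0]
    y = grid.origin[1] + idx[1] * grid.voxel_size[1]
    z = grid.origin[2] + idx[2] * grid.voxel_size[2]
    r = np.sqrt(x**2 + y**2)
    inz = np.abs(z) <= ptv_half_length
    ptv = (r <= ptv_radius) & inz
    oar = (r > ptv_radius + oar_gap) & \
          (r <= ptv_radius + oar_gap + oar_thickness) & inz
    vox_cm3 = float(np.prod(grid.voxel_size)) / 1000.0
    return {
        "PTV": StructureMask("PTV", ptv, vox_cm3),
        "OAR": StructureMask("OAR", oar, vox_cm3),
    }
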