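"""Structured voxel grids, region labels, catheter placement and distance fields.

The computational domain is a rectangular box discretized into uniform
(possibly anisotropic) cells.  Each cell carries a region label: ``tumor``,
``normal`` tissue, or ``exterior`` (air / outside the head, excluded from all
physics).  The infusion catheter occupies a single-cell-wide track of blocked
cells from the domain boundary to its tip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

TUMOR = 1
NORMAL = 0
EXTERIOR = -1


@dataclass
class StructuredGrid:
    """Uniform structured grid with per-cell region labels.

    Attributes
    ----------
    n : (3,) int array — cell counts per axis.
    h_mm : (3,) float array — cell sizes (mm).
    origin_mm : (3,) float array — coordinate of the domain corner (mm).
    region : int array of shape ``n`` — per-cell label (TUMOR / NORMAL / EXTERIOR).
    """

    n: np.ndarray
    h_mm: np.ndarray
    origin_mm: np.ndarray
    region: np.ndarray = field(default=None)

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=int)
        self.h_mm = np.asarray(self.h_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.region is None:
            self.region = np.full(tuple(self.n), NORMAL, dtype=np.int8)
        if tuple(self.region.shape) != tuple(self.n):
            raise ValueError("region label array shape does not match cell counts")

    @property
    def shape(self) -> tuple:
        return tuple(self.n)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.n))

    @property
    def cell_volume_mm3(self) -> float:
        return float(np.prod(self.h_mm))

    @property
    def cell_volume_m3(self) -> float:
        return self.cell_volume_mm3 * 1e-9

    def cell_centers_mm(self):
        """Physical coordinates of cell centers, one 3D array per axis."""
        axes = [self.origin_mm[i] + (np.arange(self.n[i]) + 0.5) * self.h_mm[i]
                for i in range(3)]
        return np.meshgrid(*axes, indexing="ij")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.region == TUMOR

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.region != EXTERIOR

    def affine(self) -> np.ndarray:
        A = np.diag(list(self.h_mm) + [1.0])
        A[:3, 3] = self.origin_mm + 0.5 * self.h_mm
        return A

    def save_field(self, values: np.ndarray, path):
        nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64),
                                 self.affine()), str(path))

    def save_meta(self, path):
        meta = {"n": self.n.tolist(), "h_mm": self.h_mm.tolist(),
                "origin_mm": self.origin_mm.tolist()}
        Path(path).write_text(json.dumps(meta, indent=1))


@dataclass
class CatheterSpec:
    """Infusion catheter: tip cell, bore and insertion axis.

    The shaft is modeled as a column of blocked (no-flow, no-flux) cells along
    ``track_axis`` from the domain boundary to the cell just before the tip;
    the tip cell itself is open tissue where the infusate enters.
    """

    tip_index: tuple
    diameter_mm: float = 0.9
    track_axis: int = 2
    track_from_high_side: bool = True
    has_track: bool = True      # False: bare point source (no blocked shaft)

    def validate(self, grid: StructuredGrid):
        tip = tuple(int(i) for i in self.tip_index)
        if len(tip) != 3 or any(i < 0 or i >= grid.n[k] for k, i in enumerate(tip)):
            raise ValueError(f"catheter tip {tip} outside the grid")
        transverse = [grid.h_mm[i] for i in range(3) if i != self.track_axis]
        if self.diameter_mm > min(transverse) + 1e-12:
            raise ValueError("catheter bore exceeds in-plane cell size")
        return tip

    def track_cells(self, grid: StructuredGrid) -> list:
        """Blocked shaft cells (excludes the tip cell)."""
        tip = self.validate(grid)
        if not self.has_track:
            return []
        ax = self.track_axis
        if self.track_from_high_side:
            rng = range(tip[ax] + 1, int(grid.n[ax]))
        else:
            rng = range(0, tip[ax])
        cells = []
        for j in rng:
            c = list(tip)
            c[ax] = j
            cells.append(tuple(c))
        return cells

    def blocked_mask(self, grid: StructuredGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        for c in self.track_cells(grid):
            m[c] = True
        return m


def build_grid(extent_mm, cell_mm, region=None) -> StructuredGrid:
    """Discretize a physical box into uniform cells.

    The per-axis cell count is the nearest integer to extent/cell with halves
    rounding up; this reproduces, e.g., a 58x97x72 mm box at 0.9x0.9x6.0 mm
    resolution as a 64x108x12 = 82,944-cell mesh.
    """
    extent_mm = np.asarray(extent_mm, dtype=float)
    cell_mm = np.asarray(cell_mm, dtype=float)
    if np.any(extent_mm <= 0) or np.any(cell_mm <= 0):
        raise ValueError("extents and cell sizes must be positive")
    n = np.floor(extent_mm / cell_mm + 0.5).astype(int)
    if np.any(n < 2):
        raise ValueError(f"grid too coarse for the FV stencil: counts {n.tolist()}")
    return StructuredGrid(n=n, h_mm=cell_mm, origin_mm=np.zeros(3), region=region)


def distance_map(grid: StructuredGrid, catheter: CatheterSpec) -> np.ndarray:
    """Euclidean distance (mm) from every cell center to the infusion-site cell center."""
    tip = catheter.validate(grid)
    X, Y, Z = grid.cell_centers_mm()
    tx = grid.origin_mm + (np.asarray(tip) + 0.5) * grid.h_mm
    return np.sqrt((X - tx[0]) ** 2 + (Y - tx[1]) ** 2 + (Z - tx[2]) ** 2)


def ellipsoid_mask(grid: StructuredGrid, center_mm, radii_mm) -> np.ndarray:
    """Boolean mask of cells whose centers lie inside an ellipsoid."""
    center_mm = np.asarray(center_mm, dtype=float)
    radii_mm = np.asarray(radii_mm, dtype=float)
    if np.any(radii_mm <= 0):
        raise ValueError("ellipsoid radii must be positive")
    X, Y, Z = grid.cell_centers_mm()
    r2 = (((X - center_mm[0]) / radii_mm[0]) ** 2
          + ((Y - center_mm[1]) / radii_mm[1]) ** 2
          + ((Z - center_mm[2]) / radii_mm[2]) ** 2)
    return r2 <= 1.0


def load_field(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
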