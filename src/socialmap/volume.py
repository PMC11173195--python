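"""Volume geometry and brain-map containers.

A :class:`VolumeGrid` couples a voxel lattice (shape), a voxel-to-mm affine
and a boolean brain mask; every simulated subject and every statistical map
lives on such a grid.  :class:`BoldRun` is one functional run's 4D time
series, :class:`StatMap` a per-voxel scalar map (AUC difference, Spearman z,
TFCE score, p value, ...).  NIfTI-1 I/O goes through nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "BoldRun", "StatMap", "default_grid"]


@dataclass
class VolumeGrid:
    """Voxel lattice with mm geometry and a brain mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> mm
    mask: np.ndarray  # boolean, same shape

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if tuple(self.mask.shape) != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_in_mask(self) -> int:
        return int(self.mask.sum())

    def mask_indices(self) -> np.ndarray:
        """In-mask voxel (i, j, k) coordinates, C-order, shape (n, 3)."""
        return np.argwhere(self.mask)

    def voxels_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            tuple(self.shape) == tuple(other.shape)
            and np.allclose(self.affine, other.affine)
            and np.array_equal(self.mask, other.mask)
        )


def default_grid(n: int = 24, spacing_mm: float = 2.4) -> VolumeGrid:
    """Isotropic ``n**3`` grid with an ellipsoidal brain mask.

    The default 24-voxel cube at 2.4 mm mirrors typical whole-brain voxel
    size while staying small enough for desk-scale simulation; the
    ellipsoid leaves a rim of out-of-brain voxels so sphere truncation at
    the mask edge is exercised.
    """
    shape = (n, n, n)
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    c = (n - 1) / 2.0
    semi = (0.46 * n, 0.42 * n, 0.40 * n)
    ii, jj, kk = np.indices(shape)
    mask = (
        ((ii - c) / semi[0]) ** 2
        + ((jj - c) / semi[1]) ** 2
        + ((kk - c) / semi[2]) ** 2
    ) <= 1.0
    return VolumeGrid(shape=shape, affine=affine, mask=mask)


@dataclass
class BoldRun:
    """One run's 4D BOLD series (x, y, z, t) on a :class:`VolumeGrid`."""

    run_id: int
    data: np.ndarray
    tr: float
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if tuple(self.data.shape[:3]) != tuple(self.grid.shape):
            raise ValueError("BOLD spatial shape does not match grid")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def frame_midpoints(self) -> np.ndarray:
        """Acquisition midpoints (i + 0.5) * TR of each volume, seconds."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.grid.affine), path)
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, tr: float, grid: VolumeGrid, run_id: int = 0) -> "BoldRun":
        img = nib.load(str(path))
        return cls(run_id=run_id, data=np.asarray(img.get_fdata()), tr=tr, grid=grid)


@dataclass
class StatMap:
    """Per-voxel scalar map; NaN outside the mask, finite inside."""

    data: np.ndarray
    grid: VolumeGrid
    tag: str = ""  # e.g. auc_minus_chance, rho, z, tfce, p
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError("map shape does not match grid")

    @classmethod
    def from_masked(cls, values: np.ndarray, grid: VolumeGrid, tag: str = "", meta: dict | None = None) -> "StatMap":
        """Build from a flat vector over ``grid.mask_indices()`` order."""
        data = np.full(grid.shape, np.nan)
        data[grid.mask] = np.asarray(values, dtype=float)
        return cls(data=data, grid=grid, tag=tag, meta=meta or {})

    def masked_values(self) -> np.ndarray:
        return self.data[self.grid.mask]

    def to_nifti(self, path: str | Path, sidecar: bool = True) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.grid.affine), path)
        if sidecar:
            side = {"tag": self.tag, **_jsonable(self.meta)}
            path.with_suffix("").with_suffix(".json").write_text(json.dumps(side, indent=1))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, grid: VolumeGrid, tag: str = "") -> "StatMap":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        side = Path(path).with_suffix("").with_suffix(".json")
        meta: dict = {}
        if side.exists():
            meta = json.loads(side.read_text())
            tag = tag or meta.pop("tag", "")
        return cls(data=data, grid=grid, tag=tag, meta=meta)


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out
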