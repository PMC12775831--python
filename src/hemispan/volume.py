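"""Masked 4D BOLD containers and hemisphere bookkeeping.

The package works on *masked* data: a volume is flattened to an
``(n_voxels, n_timepoints)`` series matrix plus per-voxel metadata
(hemisphere label, geometric-mirror index, integer coordinates).  Two
hemisphere conventions are supported:

``index_midline``
    The first array axis is split at ``shape[0] // 2``; voxel ``i`` mirrors
    to ``shape[0] - 1 - i``.  Lower indices are the left hemisphere.  This
    is the convention of the synthetic generator, where the grid is built
    symmetric by construction.

``world_x_sign``
    Left means world-space ``x < 0`` under the NIfTI affine; the mirror is
    the nearest in-mask voxel to the point with ``x`` negated.  Voxels on
    the exact midline belong to neither hemisphere and are dropped (their
    count is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

LEFT = -1
RIGHT = 1


@dataclass
class BoldVolume4D:
    """A masked 4D time-series volume with hemisphere metadata.

    Attributes
    ----------
    series : ndarray, shape (n_voxels, n_timepoints)
        One row per in-mask voxel, in the order of ``voxel_coords``.
    mask : ndarray of bool, 3D
        In-mask voxels (after midline exclusion, if any).
    hemilabel : ndarray of int, shape (n_voxels,)
        ``LEFT`` (-1) or ``RIGHT`` (+1) per voxel.
    mirror_index : ndarray of int, shape (n_voxels,)
        Row index of the geometric mirror voxel, or -1 if the mirror falls
        outside the mask.
    voxel_coords : ndarray of int, shape (n_voxels, 3)
        0-based array coordinates.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (identity for synthetic grids).
    """

    series: np.ndarray
    mask: np.ndarray
    hemilabel: np.ndarray
    mirror_index: np.ndarray
    voxel_coords: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        n = self.series.shape[0]
        if int(self.mask.sum()) != n:
            raise ValueError(
                f"series has {n} rows but mask has {int(self.mask.sum())} voxels"
            )
        if not np.all(np.isin(self.hemilabel, (LEFT, RIGHT))):
            raise ValueError("every in-mask voxel needs a hemisphere label")
        ok = self.mirror_index >= 0
        if ok.any():
            if np.any(
                self.hemilabel[self.mirror_index[ok]] == self.hemilabel[ok]
            ):
                raise ValueError("mirror of a voxel must lie in the opposite hemisphere")

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]

    def hemisphere_indices(self, side: int) -> np.ndarray:
        return np.flatnonzero(self.hemilabel == side)

    def values_to_volume(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back into a 3D array."""
        out = np.full(self.mask.shape, fill, dtype=float)
        out[tuple(self.voxel_coords.T)] = values
        return out

    @classmethod
    def from_array(
        cls,
        data4d: np.ndarray,
        mask: np.ndarray | None = None,
        convention: str = "index_midline",
        affine: np.ndarray | None = None,
    ) -> "BoldVolume4D":
        """Build a masked volume from a dense ``(x, y, z, t)`` array."""
        data4d = np.asarray(data4d, dtype=float)
        if mask is None:
            mask = np.ones(data4d.shape[:3], dtype=bool)
        if affine is None:
            affine = np.eye(4)
        kept, hemilabel, mirror_index, coords = hemisphere_split(
            mask, affine=affine, convention=convention
        )
        series = data4d[tuple(coords.T)]
        return cls(
            series=series,
            mask=kept,
            hemilabel=hemilabel,
            mirror_index=mirror_index,
            voxel_coords=coords,
            affine=np.asarray(affine, dtype=float),
        )


def hemisphere_split(
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    convention: str = "index_midline",
    midline_tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assign hemisphere labels and geometric mirrors to a mask.

    Returns ``(kept_mask, hemilabel, mirror_index, voxel_coords)`` where
    ``kept_mask`` equals ``mask`` minus any excluded midline voxels and the
    per-voxel arrays follow the row order of ``voxel_coords``
    (C-order scan of the kept mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if convention == "index_midline":
        half = mask.shape[0] // 2
        kept = mask.copy()
        if mask.shape[0] % 2:
            n_mid = int(mask[half].sum())
            if n_mid:
                logger.info("excluding %d midline-plane voxels", n_mid)
            kept[half] = False
        coords = np.argwhere(kept)
        hemilabel = np.where(coords[:, 0] < half, LEFT, RIGHT).astype(int)
        mirror_coords = coords.copy()
        mirror_coords[:, 0] = mask.shape[0] - 1 - coords[:, 0]
        mirror_index = _coords_to_rows(kept, coords, mirror_coords)
    elif convention == "world_x_sign":
        if affine is None:
            raise ValueError("world_x_sign convention requires an affine")
        coords_all = np.argwhere(mask)
        world = nib.affines.apply_affine(np.asarray(affine, float), coords_all)
        on_mid = np.abs(world[:, 0]) <= midline_tol
        if on_mid.any():
            logger.info("excluding %d exact-midline voxels", int(on_mid.sum()))
        kept = np.zeros_like(mask)
        kept[tuple(coords_all[~on_mid].T)] = True
        coords = np.argwhere(kept)
        world = nib.affines.apply_affine(np.asarray(affine, float), coords)
        hemilabel = np.where(world[:, 0] < 0, LEFT, RIGHT).astype(int)
        flipped = world.copy()
        flipped[:, 0] = -flipped[:, 0]
        mirror_index = np.full(len(coords), -1, dtype=int)
        for side in (LEFT, RIGHT):
            src = hemilabel == side
            dst = hemilabel == -side
            if not dst.any():
                continue
            tree = cKDTree(world[dst])
            _, nearest = tree.query(flipped[src])
            mirror_index[np.flatnonzero(src)] = np.flatnonzero(dst)[nearest]
    else:
        raise ValueError(f"unknown hemisphere convention: {convention!r}")
    return kept, hemilabel, mirror_index, coords


def _coords_to_rows(
    mask: np.ndarray, coords: np.ndarray, query: np.ndarray
) -> np.ndarray:
    """Map 3D coordinates to row indices of the masked flattening (-1 if absent)."""
    lut = np.full(mask.shape, -1, dtype=int)
    lut[tuple(coords.T)] = np.arange(len(coords))
    inside = np.all((query >= 0) & (query < mask.shape), axis=1)
    out = np.full(len(query), -1, dtype=int)
    out[inside] = lut[tuple(query[inside].T)]
    return out


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write an array as (uncompressed) NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def save_label_volume(path, labels: np.ndarray, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine
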