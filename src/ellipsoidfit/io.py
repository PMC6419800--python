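"""CSV and TIFF export of fitted ellipsoids.

Conventions (the on-disk contract):

* CSV: one ellipsoid per row, header row, comma delimiter, '.' decimal.
  3D columns: ``id, center_x, center_y, center_z, a1_x..a3_z (unit axis
  vectors, sign-normalized), length_1 >= length_2 >= length_3`` — 16
  numeric columns.  2D files drop the z components and the third axis.
* Coordinates are 0-based voxel indices with the voxel center at integer
  coordinates; x = column, y = row, z = slice.  3D arrays are indexed
  ``[z, y, x]``.
* Masks are multi-page TIFF, 8-bit binary (255 = interior) or 16-bit
  labels; a voxel belongs to an ellipsoid iff the quadric value at its
  center is <= 0 (no partial-volume weighting).  Overlaps resolve
  last-writer-wins.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quadrics import EllipsoidGeometry, evaluate_quadric, geometry_to_quadric

__all__ = ["write_csv", "read_csv", "write_mask", "rasterize_labels"]

logger = logging.getLogger(__name__)

_COLUMNS_3D = [
    "id",
    "center_x", "center_y", "center_z",
    "a1_x", "a1_y", "a1_z",
    "a2_x", "a2_y", "a2_z",
    "a3_x", "a3_y", "a3_z",
    "length_1", "length_2", "length_3",
]
_COLUMNS_2D = [
    "id",
    "center_x", "center_y",
    "a1_x", "a1_y",
    "a2_x", "a2_y",
    "length_1", "length_2",
]


def write_csv(
    geoms: list[EllipsoidGeometry],
    path: str | Path,
    ids: list | None = None,
) -> None:
    """Write ellipsoid parameters (center, axes, lengths) to CSV.

    All geometries must share one dimension; an empty list writes a
    header-only 3D file.  Round-trips through :func:`read_csv` losslessly
    at 12 significant digits.
    """
    dims = {g.dim for g in geoms}
    if len(dims) > 1:
        raise ValueError(f"mixed dimensions in geometry list: {sorted(dims)}")
    dim = dims.pop() if dims else 3
    cols = _COLUMNS_3D if dim == 3 else _COLUMNS_2D
    rows = []
    for k, g in enumerate(geoms):
        row = [ids[k] if ids is not None else k]
        row += list(g.center)
        for j in range(dim):
            row += list(g.axes[:, j])
        row += list(g.semilengths)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.15g")


def read_csv(path: str | Path) -> tuple[list[EllipsoidGeometry], list]:
    """Read a parameter CSV back into geometries (inverse of write_csv)."""
    df = pd.read_csv(path)
    dim = 3 if "center_z" in df.columns else 2
    cols = _COLUMNS_3D if dim == 3 else _COLUMNS_2D
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    geoms, ids = [], []
    for _, row in df.iterrows():
        center = row[[f"center_{ax}" for ax in "xyz"[:dim]]].to_numpy(float)
        axes = np.column_stack(
            [
                row[[f"a{j + 1}_{ax}" for ax in "xyz"[:dim]]].to_numpy(float)
                for j in range(dim)
            ]
        )
        lengths = row[[f"length_{j + 1}" for j in range(dim)]].to_numpy(float)
        geoms.append(
            EllipsoidGeometry(center=center, axes=axes, semilengths=lengths)
        )
        ids.append(row["id"])
    return geoms, ids


def rasterize_labels(
    geoms: list[EllipsoidGeometry], shape: tuple[int, int, int]
) -> np.ndarray:
    """Label image (uint16, indexed ``[z, y, x]``) of ellipsoid interiors.

    Voxel-center rule; labels are 1-based list positions, overlaps are
    last-writer-wins (overlap voxel count is logged).  Ellipsoids outside
    the volume are clipped and contribute nothing where clipped.
    """
    shape = tuple(int(s) for s in shape)
    mask = np.zeros(shape, dtype=np.uint16)
    overlap = 0
    for label, geom in enumerate(geoms, start=1):
        quad = geometry_to_quadric(geom)
        r = geom.semilengths[0]
        # bounding box in (x, y, z); array index order is (z, y, x)
        lo_xyz = np.floor(geom.center - r).astype(int)
        hi_xyz = np.ceil(geom.center + r).astype(int) + 1
        lo = np.maximum(lo_xyz[::-1], 0)
        hi = np.minimum(hi_xyz[::-1], shape)
        if np.any(lo >= hi):
            logger.warning("ellipsoid %d lies outside the volume", label)
            continue
        zz, yy, xx = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
        )
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1).astype(float)
        # <= 0 with a guard so voxel centers exactly on the surface are
        # included regardless of rounding in the trace normalization
        inside = evaluate_quadric(quad, pts) <= 1e-9
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        box = mask[sub].ravel()
        overlap += int(np.count_nonzero(box[inside]))
        box[inside] = label
        mask[sub] = box.reshape(mask[sub].shape)
    if overlap:
        logger.warning("labeled mask: %d voxels overwritten by overlaps", overlap)
    return mask


def write_mask(
    geoms: list[EllipsoidGeometry],
    image_shape: tuple[int, int, int],
    path: str | Path,
    labeled: bool = False,
) -> np.ndarray:
    """Write the interior mask of the ellipsoids as a multi-page TIFF.

    Binary mode writes uint8 (255 inside); labeled mode writes uint16
    with the 1-based index of the last containing ellipsoid.  Returns the
    array written.
    """
    mask = rasterize_labels(geoms, image_shape)
    if labeled:
        out = mask
    else:
        out = np.where(mask > 0, np.uint8(255), np.uint8(0))
    tifffile.imwrite(path, out)
    return out
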