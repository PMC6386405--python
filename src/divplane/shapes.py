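"""Calibrated binary cell masks: synthetic shapes, label-image I/O, resampling.

A cell is represented on a regular voxel (or pixel) grid as a boolean
occupancy array together with the physical edge lengths of one voxel.
All downstream geometry (meshes, centroids, distances) is expressed in
micrometers; grid indices map to physical coordinates through the
calibration and an origin offset (the physical position of the center of
voxel ``(0, 0, 0)``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration",
    "CellMask",
    "digitize_shape",
    "read_label_stack",
    "write_label_stack",
    "resample_to_cubic",
]


@dataclass(frozen=True)
class Calibration:
    """Physical edge lengths of one voxel, in micrometers per axis.

    Axis order matches array index order: axis 0 -> x, axis 1 -> y,
    axis 2 -> z (for 2D grids only x and y are used).
    """

    voxel_size_x: float
    voxel_size_y: float
    voxel_size_z: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.voxel_size_x, self.voxel_size_y, self.voxel_size_z):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"voxel sizes must be strictly positive, got {v}")

    @classmethod
    def cubic(cls, side: float) -> "Calibration":
        return cls(side, side, side)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([self.voxel_size_x, self.voxel_size_y, self.voxel_size_z])

    @property
    def is_cubic(self) -> bool:
        s = self.sizes
        return bool(np.all(np.abs(s - s[0]) <= 1e-9 * s[0]))

    @property
    def side(self) -> float:
        """Edge length for cubic calibrations."""
        if not self.is_cubic:
            raise ValueError("calibration is not cubic")
        return self.voxel_size_x

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.sizes))

    @property
    def voxel_diagonal(self) -> float:
        """Length of the voxel body diagonal, sqrt(dx^2 + dy^2 + dz^2)."""
        return float(np.sqrt(np.sum(self.sizes**2)))


@dataclass
class CellMask:
    """Binary occupancy grid of one mother cell, with physical calibration.

    ``occupancy`` is a 3D (or 2D) boolean array; ``origin_offset`` gives the
    physical coordinate (um) of the center of voxel index ``(0, ..., 0)``.
    """

    occupancy: np.ndarray
    calibration: Calibration
    origin_offset: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim not in (2, 3):
            raise ValueError("occupancy must be a 2D or 3D array")
        if self.origin_offset is None:
            self.origin_offset = np.zeros(self.occupancy.ndim)
        self.origin_offset = np.asarray(self.origin_offset, dtype=float)
        if self.origin_offset.shape != (self.occupancy.ndim,):
            raise ValueError("origin_offset must have one entry per grid axis")
        if self.n_sites == 0:
            raise ValueError("mask has no occupied site")
        self._warn_if_fragmented()

    def _warn_if_fragmented(self) -> None:
        structure = ndimage.generate_binary_structure(self.occupancy.ndim, 1)
        _, n = ndimage.label(self.occupancy, structure=structure)
        if n > 1:
            warnings.warn(
                f"mask is not face-connected ({n} components); proceeding anyway",
                stacklevel=3,
            )

    @property
    def ndim(self) -> int:
        return self.occupancy.ndim

    @property
    def n_sites(self) -> int:
        return int(self.occupancy.sum())

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (um) for the grid axes actually present."""
        return self.calibration.sizes[: self.ndim]

    @property
    def volume(self) -> float:
        """Occupied physical volume in um^3 (um^2 in 2D)."""
        return self.n_sites * float(np.prod(self.spacing))

    def centroid(self) -> np.ndarray:
        """Physical centroid (um) of the occupied sites."""
        idx = np.argwhere(self.occupancy)
        return self.origin_offset + idx.mean(axis=0) * self.spacing

    def to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Convert (fractional) grid indices to physical coordinates (um)."""
        return self.origin_offset + np.asarray(indices, dtype=float) * self.spacing


_SHAPE_KINDS = ("sphere", "half_sphere", "quarter_sphere", "truncated_sphere")


def digitize_shape(
    kind: str,
    radius: float,
    calibration: Calibration,
    truncation_fraction: float = 0.25,
) -> CellMask:
    """Digitize a continuous reference shape onto a voxel grid.

    A voxel is occupied iff its center lies strictly inside the continuous
    shape. Along axes carrying a planar cut (z for half and truncated
    spheres; y and z for quarter spheres) the shape center sits on a voxel
    corner, so the cut falls exactly between voxel layers and the derived
    shapes are clean fractions of a sphere; other axes center on a voxel
    center, which minimizes digitization error. A 2-voxel empty margin
    surrounds the shape.

    Parameters
    ----------
    kind:
        One of ``sphere``, ``half_sphere``, ``quarter_sphere``,
        ``truncated_sphere``.
    radius:
        Sphere radius in um. Must be at least 3 voxel side lengths.
    truncation_fraction:
        For ``truncated_sphere`` only: fraction of the *diameter* removed
        by a single planar cut perpendicular to the z axis (default 0.25,
        i.e. the cut plane sits at height +R/2 above the center).
    """
    if kind not in _SHAPE_KINDS:
        raise ValueError(f"unknown shape kind {kind!r}; expected one of {_SHAPE_KINDS}")
    sizes = calibration.sizes
    if radius < 3 * sizes.max():
        raise ValueError("shape too small to discretize (radius below 3 voxels)")
    if kind == "truncated_sphere" and not (0 < truncation_fraction < 1):
        raise ValueError("truncation_fraction must lie in (0, 1)")

    # grid extent: diameter plus a 2-voxel margin on each side
    n = np.ceil(2 * radius / sizes).astype(int) + 5
    # the center sits between voxel layers (corner) along z for every
    # kind -- so a half-sphere is an exact restriction of the digitized
    # sphere -- and additionally along y for the quarter sphere
    cut_axes = (1, 2) if kind == "quarter_sphere" else (2,)
    center = (n // 2).astype(float) * sizes
    for ax in cut_axes:
        center[ax] += 0.5 * sizes[ax]
    coords = [np.arange(n[d]) * sizes[d] for d in range(3)]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    inside = dx**2 + dy**2 + dz**2 < radius**2
    if kind == "half_sphere":
        inside &= dz > 0
    elif kind == "quarter_sphere":
        inside &= (dz > 0) & (dy > 0)
    elif kind == "truncated_sphere":
        inside &= dz < radius * (1.0 - 2.0 * truncation_fraction)
    occ = _crop_to_margin(inside, margin=2)
    return CellMask(occ, calibration)


def _crop_to_margin(occ: np.ndarray, margin: int) -> np.ndarray:
    """Crop a boolean array to its bounding box plus a fixed empty margin."""
    idx = np.argwhere(occ)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    slices = tuple(slice(l, h) for l, h in zip(lo, hi))
    core = occ[slices]
    return np.pad(core, margin)


def write_label_stack(path, masks_or_labels, calibration: Calibration) -> None:
    """Write a 3D integer label image (0 = background) as a multi-page TIFF.

    ``masks_or_labels`` is either an integer label array or a list of
    CellMasks sharing one grid (labelled 1..n in list order). Calibration is
    stored in a sidecar JSON file ``<path>.json``.
    """
    path = Path(path)
    if isinstance(masks_or_labels, np.ndarray):
        labels = masks_or_labels
    else:
        masks = list(masks_or_labels)
        labels = np.zeros(masks[0].occupancy.shape, dtype=np.uint16)
        for i, m in enumerate(masks, start=1):
            labels[m.occupancy] = i
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label image must have an integer dtype")
    # tifffile pages run along the first axis; store as (z, y, x)
    tifffile.imwrite(path, np.ascontiguousarray(np.moveaxis(labels, 2, 0)))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"voxel_size_um": list(map(float, calibration.sizes))})
    )


def read_label_stack(path, calibration: Calibration | None = None) -> list[CellMask]:
    """Read a segmented label TIFF into one CellMask per nonzero label.

    Calibration is taken from the sidecar JSON written by
    :func:`write_label_stack` unless given explicitly. Labels are returned
    in increasing label order.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"expected integer labels, got dtype {data.dtype}")
    if calibration is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                "no calibration supplied and no sidecar JSON found "
                f"({sidecar.name})"
            )
        meta = json.loads(sidecar.read_text())
        calibration = Calibration(*meta["voxel_size_um"])
    if data.ndim == 3:
        data = np.moveaxis(data, 0, 2)  # pages are z; back to (x, y, z)
    values = np.unique(data)
    values = values[values != 0]
    if values.size == 0:
        logger.warning("label stack %s contains no nonzero label", path)
        return []
    return [CellMask(data == v, calibration) for v in values]


def resample_to_cubic(mask: CellMask) -> CellMask:
    """Resample an anisotropic mask to cubic voxels (nearest-neighbor).

    The cubic side is the largest input edge length, so the grid only ever
    coarsens. The binary mask is interpolated linearly and binarized by a
    volume-preserving rank threshold: the k voxels with the highest
    interpolated occupancy are kept, k chosen so the occupied physical
    volume matches the input to within one voxel. The output stays
    strictly binary and the threshold adapts instead of quantizing whole
    boundary layers in or out.
    """
    if mask.calibration.is_cubic:
        return mask
    side = float(mask.spacing.max())
    zoom = mask.spacing / side
    vals = ndimage.zoom(
        mask.occupancy.astype(np.float32),
        zoom,
        order=1,
        grid_mode=True,
        mode="grid-constant",
    )
    k = int(np.clip(np.round(mask.volume / side ** mask.ndim), 1, vals.size))
    flat = vals.ravel()
    order = np.argsort(-flat, kind="stable")
    occ = np.zeros(flat.size, dtype=bool)
    occ[order[:k]] = True
    occ = occ.reshape(vals.shape)
    new_cal = Calibration.cubic(side)
    if mask.ndim == 2:
        new_cal = Calibration(side, side, mask.calibration.voxel_size_z)
    return CellMask(occ.astype(bool), new_cal, mask.origin_offset.copy())
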