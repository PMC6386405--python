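"""2D division model for leaf epidermal cells: exchange dynamics.

In the planar variant the volume(area)-ratio constraint is not an energy
term: the initial assignment is generated exactly at the target ratio and
every Metropolis move exchanges one site of each daughter (Kawasaki
dynamics), so the ratio is conserved to the voxel at every step. The
energy reduces to the interface term, counted over the 8-neighborhood in
direct analogy with the 26-neighborhood used in 3D.

Exchange proposals pick one uniformly random site from each daughter (the
sites need not be adjacent); acceptance follows the usual Metropolis rule
on the interface-energy change. By default the temperature is annealed
over the run (see :func:`metropolis_division_2d`), which lets elongated
cells escape multi-band local minima; passing an explicit ``kT`` runs at
fixed temperature instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

from . import _kernels
from .division3d import ModelParams
from .shapes import CellMask

__all__ = [
    "Partition2D",
    "Interface2D",
    "init_partition_at_ratio",
    "metropolis_division_2d",
    "interface_energy_2d",
]



@dataclass
class Partition2D:
    """Binary partition of a 2D mask with exactly conserved daughter areas."""

    mask: CellMask
    site_labels: np.ndarray
    site_indices: np.ndarray = None  # type: ignore[assignment]
    nbr_ptr: np.ndarray = None  # type: ignore[assignment]
    nbr_idx: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.site_labels = np.asarray(self.site_labels, dtype=np.int8)
        if self.site_indices is None:
            self.site_indices, self.nbr_ptr, self.nbr_idx = _kernels.build_adjacency(
                self.mask.occupancy
            )

    @property
    def n_sites(self) -> int:
        return self.site_labels.size

    @property
    def v1(self) -> int:
        return int(np.count_nonzero(self.site_labels == 1))

    @property
    def v2(self) -> int:
        return self.n_sites - self.v1

    @property
    def labels_grid(self) -> np.ndarray:
        grid = np.zeros(self.mask.occupancy.shape, dtype=np.int8)
        grid[tuple(self.site_indices.T)] = self.site_labels
        return grid


@dataclass
class Interface2D:
    """Measures of the 1D division interface of a 2D partition.

    Two lengths are reported: ``pair_length`` (discordant 8-neighbor pair
    count x pixel side, the quantity the energy sees) and ``length`` (the
    marching-squares polyline length, the measurement-consistent value
    used in rule evaluation; facet counting overestimates oblique
    interfaces, a polyline does not).
    """

    length: float
    pair_length: float
    anchor_distance: float
    area_ratio: float
    contour_points: np.ndarray


def init_partition_at_ratio(
    mask2d: CellMask, rho_star: float, seed: int = 0
) -> Partition2D:
    """Random assignment with v1 = round(rho_star * N) exactly.

    Rounding is numpy's round-half-even. Which sites get daughter 1 is a
    uniform random subset; two calls with the same seed agree exactly.
    """
    if mask2d.ndim != 2:
        raise ValueError("expected a 2D mask")
    if not 0 < rho_star < 1:
        raise ValueError("rho_star must lie strictly between 0 and 1")
    n = mask2d.n_sites
    v1 = int(np.round(rho_star * n))
    if v1 == 0 or v1 == n:
        raise ValueError("target ratio leaves one daughter empty at this resolution")
    rng = np.random.default_rng(seed)
    labels = np.full(n, 2, dtype=np.int8)
    labels[rng.choice(n, size=v1, replace=False)] = 1
    return Partition2D(mask2d, labels)


def interface_energy_2d(partition: Partition2D, params: ModelParams) -> float:
    """alpha a^2 x discordant 8-neighbor pair count (unordered)."""
    params = params.resolve(partition.mask)
    pairs = _kernels.discordant_pairs(
        partition.site_labels, partition.nbr_ptr, partition.nbr_idx
    )
    return params.alpha_a2 * pairs


def metropolis_division_2d(
    mask2d: CellMask,
    params: ModelParams,
    nucleus: np.ndarray | None = None,
) -> tuple[Partition2D, Interface2D, np.ndarray]:
    """Run one ratio-conserving 2D division.

    Returns (partition, interface measures, per-cycle energy trace). The
    anchor for the interface distance is ``nucleus`` (um) when given, the
    mask centroid otherwise.
    """
    if mask2d.ndim != 2:
        raise ValueError("expected a 2D mask")
    part = init_partition_at_ratio(mask2d, params.rho_star, params.seed)
    resolved = params.resolve(mask2d)
    eps = resolved.alpha_a2
    if params.kT is None:
        # conserved (Kawasaki) dynamics relax poorly at fixed temperature in
        # elongated shapes (parallel-band local minima); the default anneals
        # slowly through the order-disorder region (linear 2.2 eps -> 0.8 eps)
        # then quenches geometrically to eps/4, which reliably merges bands
        schedule = eps * np.r_[np.linspace(2.2, 0.8, 15), np.geomspace(0.7, 0.25, 5)]
    else:
        schedule = np.array([resolved.kT])
    per_stage = max(1, params.n_cycles // len(schedule))
    traces = []
    for stage, kT in enumerate(schedule):
        kernel_seed = int(
            np.random.SeedSequence([params.seed, stage]).generate_state(2)[1]
            & 0x7FFFFFFF
        )
        _, tr = _kernels.metropolis_exchange(
            part.site_labels,
            part.nbr_ptr,
            part.nbr_idx,
            eps,
            float(kT),
            per_stage,
            kernel_seed,
        )
        traces.append(tr)
    anchor = np.asarray(nucleus, float) if nucleus is not None else mask2d.centroid()
    iface = measure_interface_2d(part, anchor)
    return part, iface, np.concatenate(traces)


def measure_interface_2d(partition: Partition2D, anchor: np.ndarray) -> Interface2D:
    """Extract the interface polyline (marching squares) and measure it."""
    mask = partition.mask
    side = float(mask.spacing[0])
    pairs = _kernels.discordant_pairs(
        partition.site_labels, partition.nbr_ptr, partition.nbr_idx
    )
    # nearest-label fill of the background, as in the 3D mesh extraction
    from scipy import ndimage

    labels = partition.labels_grid
    _, idx = ndimage.distance_transform_edt(
        ~mask.occupancy, sampling=mask.spacing, return_indices=True
    )
    filled = labels[idx[0], idx[1]]
    indicator = (filled == 1).astype(float)
    contours = skmeasure.find_contours(np.pad(indicator, 1, mode="edge"), 0.5)
    total = 0.0
    min_d = np.inf
    kept = []
    anchor_idx = (np.asarray(anchor, float) - mask.origin_offset) / mask.spacing
    for c in contours:
        c = c - 1.0  # undo pad
        mid = 0.5 * (c[:-1] + c[1:])
        seg_keep = mask.occupancy[
            tuple(
                np.clip(np.round(mid).astype(int), 0, np.array(mask.occupancy.shape) - 1).T
            )
        ]
        seg_len = np.linalg.norm(np.diff(c, axis=0), axis=1) * side
        total += float(seg_len[seg_keep].sum())
        pts = c[np.r_[seg_keep, False] | np.r_[False, seg_keep]]
        if pts.size:
            kept.append(pts)
            d = _min_point_polyline_distance(anchor_idx, pts) * side
            min_d = min(min_d, d)
    v1, v2 = partition.v1, partition.v2
    return Interface2D(
        length=total,
        pair_length=pairs * side,
        anchor_distance=float(min_d) if np.isfinite(min_d) else float("nan"),
        area_ratio=min(v1, v2) / (v1 + v2),
        contour_points=np.concatenate(kept, axis=0) if kept else np.empty((0, 2)),
    )


def _min_point_polyline_distance(p: np.ndarray, poly: np.ndarray) -> float:
    """Min distance from point to a polyline given as ordered vertices."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - p, axis=1)
    vert = np.linalg.norm(poly - p, axis=1)
    return float(min(d.min(initial=np.inf), vert.min(initial=np.inf)))
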