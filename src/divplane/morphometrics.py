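"""Per-cell 3D morphometry: 16 scalar features of a binary cell mask.

Size features: volume, wall surface area, mean breadth, the three axis
lengths of the equivalent inertia ellipsoid, the radius of the maximal
inscribed ball and the geodesic diameter. Shape features: three
dimensionless size-ratio factors (each normalized to 1 for a ball), three
elongation factors (ratios of sorted ellipsoid axes), convexity (volume
over convex-hull volume) and geodesic elongation (geodesic diameter over
inscribed-ball diameter).

Surface area comes from a 13-direction Cauchy-Crofton estimator (naive
exposed-facet counting is orientation-biased by up to 50%); mean breadth
from the integral of mean curvature of the marching-cubes surface. Both
are accurate to a few percent on digitized balls of radius >= 10 voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure

from .shapes import CellMask

__all__ = [
    "MorphometricRecord",
    "cell_morphometrics",
    "morphometrics_table",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "volume",
    "surface_area",
    "mean_breadth",
    "ellipsoid_axis_1",
    "ellipsoid_axis_2",
    "ellipsoid_axis_3",
    "inscribed_ball_radius",
    "geodesic_diameter",
    "shape_factor_sphericity",
    "shape_factor_breadth_area",
    "shape_factor_breadth_volume",
    "elongation_major_median",
    "elongation_median_minor",
    "elongation_major_minor",
    "convexity",
    "geodesic_elongation",
)


@dataclass(frozen=True)
class MorphometricRecord:
    """The 16 morphometric features of one cell, all in um-based units."""

    volume: float  # um^3
    surface_area: float  # um^2
    mean_breadth: float  # um
    ellipsoid_axis_1: float  # um, major
    ellipsoid_axis_2: float  # um, median
    ellipsoid_axis_3: float  # um, minor
    inscribed_ball_radius: float  # um
    geodesic_diameter: float  # um
    shape_factor_sphericity: float  # 36 pi V^2 / S^3, 1 for a ball
    shape_factor_breadth_area: float  # S / (pi b^2), 1 for a ball
    shape_factor_breadth_volume: float  # 6 V / (pi b^3), 1 for a ball
    elongation_major_median: float
    elongation_median_minor: float
    elongation_major_minor: float
    convexity: float
    geodesic_elongation: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def cell_morphometrics(mask: CellMask) -> MorphometricRecord:
    """Compute all 16 features for one cell mask. Deterministic.

    The mask should be a single face-connected component (a warning is
    raised at construction otherwise); features are computed on the mask
    as given.
    """
    if mask.ndim != 3:
        raise ValueError("morphometrics are defined for 3D masks")
    occ = mask.occupancy
    spacing = mask.calibration.sizes
    volume = mask.n_sites * float(np.prod(spacing))

    surface_area, mean_breadth = _surface_and_breadth(occ, spacing)
    axes = _inertia_ellipsoid_axes(occ, spacing)
    r_in = _inscribed_ball_radius(occ, spacing)
    g_diam = _geodesic_diameter(occ, spacing)

    b = mean_breadth
    return MorphometricRecord(
        volume=volume,
        surface_area=surface_area,
        mean_breadth=b,
        ellipsoid_axis_1=axes[0],
        ellipsoid_axis_2=axes[1],
        ellipsoid_axis_3=axes[2],
        inscribed_ball_radius=r_in,
        geodesic_diameter=g_diam,
        shape_factor_sphericity=36.0 * np.pi * volume**2 / surface_area**3,
        shape_factor_breadth_area=surface_area / (np.pi * b**2),
        shape_factor_breadth_volume=6.0 * volume / (np.pi * b**3),
        elongation_major_median=axes[0] / axes[1],
        elongation_median_minor=axes[1] / axes[2],
        elongation_major_minor=axes[0] / axes[2],
        convexity=_convexity(occ, spacing, volume),
        geodesic_elongation=g_diam / (2.0 * r_in),
    )


def _mask_mesh(occ: np.ndarray, spacing: np.ndarray) -> trimesh.Trimesh:
    padded = np.pad(occ, 1).astype(np.float32)
    verts, faces, _, _ = skmeasure.marching_cubes(
        padded, level=0.5, spacing=tuple(spacing)
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


_CROFTON_DIRECTIONS = tuple(
    t
    for t in (
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    )
)


def _crofton_weights(spacing: np.ndarray) -> np.ndarray:
    """Solid-angle fraction of the sphere owned by each direction family.

    Computed as the spherical-Voronoi areas of the 26 lattice directions
    (13 antipodal pairs), scaled by the physical spacing so anisotropic
    grids get correct weights.
    """
    from scipy.spatial import SphericalVoronoi

    dirs = np.array(_CROFTON_DIRECTIONS, dtype=float) * spacing
    dirs = np.concatenate([dirs, -dirs])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    sv = SphericalVoronoi(dirs, radius=1.0)
    areas = sv.calculate_areas()
    return (areas[:13] + areas[13:]) / (4.0 * np.pi)


def crofton_surface_area(occ: np.ndarray, spacing: np.ndarray) -> float:
    """Surface area by the Cauchy-Crofton formula over 13 line directions.

    For each lattice direction t, the number of consecutive voxel pairs
    (p, p + t) with differing occupancy counts line-surface crossings;
    each line owns a perpendicular cross-section v / |t| (v the voxel
    volume), and isotropic averaging gives S = 2 sum_d w_d C_d v / l_d.
    Accurate to ~1-2% for balls of radius >= 10 voxels (facet counting
    along the 3 axes alone is orientation-biased by up to 50%).
    """
    occ = np.asarray(occ, bool)
    weights = _crofton_weights(spacing)
    v = float(np.prod(spacing))
    padded = np.pad(occ, 2)
    total = 0.0
    for w, t in zip(weights, _CROFTON_DIRECTIONS):
        shifted = np.roll(padded, shift=tuple(-x for x in t), axis=(0, 1, 2))
        # one mismatch per discordant pair (p, p + t), registered at p
        crossings = int(np.count_nonzero(padded != shifted))
        length = float(np.linalg.norm(np.array(t) * spacing))
        total += w * crossings * (v / length)
    return 2.0 * total


def _surface_and_breadth(occ: np.ndarray, spacing: np.ndarray) -> tuple[float, float]:
    area = crofton_surface_area(occ, spacing)
    # mean breadth b = M / (2 pi), M the integral of mean curvature of the
    # marching-cubes surface (sum over edges of length x dihedral / 2);
    # 2R for a ball, with a known staircase overestimate of a few percent
    mesh = _mask_mesh(occ, spacing)
    imc = abs(float(mesh.integral_mean_curvature))
    return area, imc / (2.0 * np.pi)


def _inertia_ellipsoid_axes(occ: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    pts = np.argwhere(occ) * spacing
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / pts.shape[0]
    # add the second moment of a unit voxel (parallel-axis correction)
    cov += np.diag(spacing**2) / 12.0
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    # uniform solid ellipsoid with semi-axis s has variance s^2/5 per axis
    return 2.0 * np.sqrt(5.0 * np.clip(evals, 0.0, None))


def _inscribed_ball_radius(occ: np.ndarray, spacing: np.ndarray) -> float:
    edt = ndimage.distance_transform_edt(occ, sampling=spacing)
    return float(edt.max())


def _geodesic_offsets() -> np.ndarray:
    """26-neighborhood plus knight moves (chamfer 5x5x5 stencil).

    Offsets within max-norm 2, excluding collinear doubles of shorter
    steps; the knight moves cut the metrication error of the chamfer
    metric from ~7% to ~2%.
    """
    offs = []
    for o in np.ndindex(5, 5, 5):
        o = np.array(o) - 2
        m = np.max(np.abs(o))
        if m == 0:
            continue
        if np.gcd.reduce(np.abs(o)) > 1:  # collinear with a shorter step
            continue
        offs.append(o)
    return np.array(offs)


def _geodesic_diameter(occ: np.ndarray, spacing: np.ndarray) -> float:
    """Longest shortest path between voxel centers inside the mask.

    Shortest paths run on the voxel graph with Euclidean step weights
    over a knight-augmented neighborhood (steps up to max-norm 2; a
    length-2 step is admitted only when both voxels next to its midpoint
    are inside, so paths cannot tunnel through walls). The diameter is
    approximated by iterated farthest-point sweeps from the inscribed-
    ball center -- exact for convex shapes, a tight lower bound otherwise.
    """
    from scipy.sparse import csr_matrix

    occ = np.asarray(occ, bool)
    site_indices = np.argwhere(occ)
    n = site_indices.shape[0]
    if n == 1:
        return float(np.min(spacing))
    site_id = -np.ones(occ.shape, dtype=np.int64)
    site_id[occ] = np.arange(n)
    pad = 2
    pid = np.pad(site_id, pad, constant_values=-1)
    pocc = np.pad(occ, pad)
    base = site_indices + pad
    rows, cols, wts = [], [], []
    for o in _geodesic_offsets():
        tgt = base + o
        ok = pid[tuple(tgt.T)] >= 0
        if np.max(np.abs(o)) == 2:
            h1 = base + np.floor(o / 2.0).astype(int)
            h2 = base + np.ceil(o / 2.0).astype(int)
            ok &= pocc[tuple(h1.T)] & pocc[tuple(h2.T)]
        idx = np.nonzero(ok)[0]
        rows.append(idx)
        cols.append(pid[tuple(tgt[idx].T)])
        wts.append(np.full(idx.size, np.linalg.norm(o * spacing)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    wts = np.concatenate(wts)
    graph = csr_matrix((wts, (rows, cols)), shape=(n, n))
    edt = ndimage.distance_transform_edt(occ, sampling=spacing)
    start = int(np.argmax(edt[tuple(site_indices.T)]))
    best = 0.0
    for _ in range(3):  # farthest-point sweeps
        dist = dijkstra(graph, directed=False, indices=start)
        far = int(np.argmax(dist))
        if dist[far] <= best:
            break
        best = float(dist[far])
        start = far
    return best


def _convexity(occ: np.ndarray, spacing: np.ndarray, volume: float) -> float:
    pts = np.argwhere(occ) * spacing
    if pts.shape[0] < 5:
        return 1.0
    # hull over voxel centers: for a digitized convex body the center hull
    # slightly underestimates the voxelized volume, so the ratio is
    # clipped at 1 (convexity is defined on (0, 1])
    try:
        hull = ConvexHull(pts)
    except Exception:
        warnings.warn("convex hull failed; convexity set to NaN")
        return float("nan")
    return min(volume / hull.volume, 1.0)


def morphometrics_table(masks, labels=None):
    """Feature table for a collection of cells: one row per cell.

    Returns a pandas DataFrame with a stable column order (FEATURE_NAMES)
    indexed by ``labels`` (default: integer position). Write with
    ``df.to_csv(path)`` for the standard per-cell CSV export.
    """
    import pandas as pd

    rows = [cell_morphometrics(m).as_dict() for m in masks]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        df.index = list(labels)
        df.index.name = "cell"
    return df
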