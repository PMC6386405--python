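"""Division-interface extraction and plane-level geometry.

The interface between the two daughters of a partition is extracted as a
triangular mesh (marching cubes on the daughter-1 indicator), restricted
to the interior of the mother cell so the mother's outer wall never
contributes. All measurements — total area, area-weighted unit normal,
mesh centroid, exact closest-point distance to an anchor, orientation
angles — are carried out in physical micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .division3d import Partition
from .shapes import Calibration

__all__ = [
    "DivisionMesh",
    "PlaneMeasures",
    "extract_interface_mesh",
    "plane_summary",
    "measure_division",
    "volume_ratio",
    "inter_plane_angle",
    "point_mesh_distance",
]


@dataclass
class DivisionMesh:
    """Triangulated division interface, in physical um coordinates.

    Triangle normals follow a fixed sign convention: they point from
    daughter 1 toward daughter 2. All reported angles downstream are
    folded to [0, 90] degrees, so the convention never affects results.
    """

    vertices: np.ndarray  # (n_vertices, 3) um
    triangles: np.ndarray  # (n_triangles, 3) vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.shape[0] < 1:
            raise ValueError("mesh must contain at least one triangle")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")
        tri = self.vertices[self.triangles]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        self._areas = 0.5 * np.linalg.norm(cross, axis=1)
        keep = self._areas > 1e-300
        if not np.all(keep):  # drop degenerate slivers from marching cubes
            self.triangles = self.triangles[keep]
            self._areas = self._areas[keep]
            cross = cross[keep]
            if self.triangles.shape[0] < 1:
                raise ValueError("mesh has no non-degenerate triangle")
        self._normals = cross / (2.0 * self._areas)[:, None]

    @property
    def triangle_areas(self) -> np.ndarray:
        return self._areas

    @property
    def triangle_normals(self) -> np.ndarray:
        return self._normals

    @property
    def area(self) -> float:
        return float(self._areas.sum())

    @property
    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def export(self, path) -> None:
        """Write the mesh as PLY or OFF (by file extension)."""
        import trimesh

        trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        ).export(path)


@dataclass
class PlaneMeasures:
    """Scalar summary of one division plane."""

    area: float
    unit_normal: np.ndarray
    mesh_centroid: np.ndarray
    anchor_distance: float
    volume_ratio: float
    orientation_angle: float = float("nan")
    n_components_d1: int = 1
    n_components_d2: int = 1
    degenerate_normal: bool = False

    @property
    def fragmented(self) -> bool:
        return self.n_components_d1 > 1 or self.n_components_d2 > 1

    def to_dict(self) -> dict:
        return {
            "area": self.area,
            "unit_normal": list(map(float, self.unit_normal)),
            "mesh_centroid": list(map(float, self.mesh_centroid)),
            "anchor_distance": self.anchor_distance,
            "volume_ratio": self.volume_ratio,
            "orientation_angle": self.orientation_angle,
            "n_components_d1": self.n_components_d1,
            "n_components_d2": self.n_components_d2,
            "degenerate_normal": self.degenerate_normal,
        }


def extract_interface_mesh(
    partition: Partition, calibration: Calibration | None = None
) -> DivisionMesh:
    """Extract the daughter-1/daughter-2 interface as a triangular mesh.

    The mesh is the 0.5-level surface of the daughter-1 indicator.
    Background voxels are first filled with the label of their nearest
    occupied site, which closes the indicator field smoothly across the
    mother wall; triangles whose centroid falls outside the mother mask
    are then discarded, so only the interior interface remains.
    Deterministic for a given partition.
    """
    if calibration is None:
        calibration = partition.mask.calibration
    labels = partition.labels_grid
    if partition.v1 == 0 or partition.v2 == 0:
        raise ValueError("no interface: partition has a single label")
    occ = partition.mask.occupancy
    # nearest-site label fill of the background
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~occ, sampling=calibration.sizes[:3], return_indices=True
    )
    filled = labels[ix, iy, iz]
    indicator = (filled == 1).astype(np.float32)
    indicator = np.pad(indicator, 1, mode="edge")
    spacing = tuple(calibration.sizes[:3])
    verts, faces, normals, _ = skmeasure.marching_cubes(
        indicator, level=0.5, spacing=spacing
    )
    verts_grid = verts / np.asarray(spacing) - 1.0  # undo pad, back to index space
    tri_centroids = verts_grid[faces].mean(axis=1)
    nearest = np.clip(
        np.round(tri_centroids).astype(int), 0, np.asarray(occ.shape) - 1
    )
    inside = occ[tuple(nearest.T)]
    faces = faces[inside]
    if faces.shape[0] == 0:
        raise ValueError("no interface triangles inside the mother mask")
    verts_um = partition.mask.origin_offset + verts_grid * calibration.sizes[:3]
    mesh = DivisionMesh(verts_um, faces)
    _orient_towards_daughter2(mesh, normals, faces)
    return mesh


def _orient_towards_daughter2(mesh: DivisionMesh, vertex_normals, faces) -> None:
    """Flip triangle windings so normals point from daughter 1 to daughter 2.

    Marching cubes returns vertex normals along the descending gradient of
    the indicator (towards the 0 side, i.e. daughter 2); triangle normals
    are aligned with the mean vertex normal of each face.
    """
    ref = vertex_normals[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", mesh.triangle_normals, ref) < 0
    mesh.triangles[flip] = mesh.triangles[flip][:, ::-1]
    mesh._normals[flip] *= -1.0


def point_mesh_distance(point: np.ndarray, mesh: DivisionMesh) -> tuple[float, np.ndarray]:
    """Exact minimum Euclidean distance from a point to the mesh surface.

    Computed per triangle with the standard closest-point-on-triangle
    projection (not vertex-only). Returns (distance, closest_point).
    """
    p = np.asarray(point, dtype=float)
    tri = mesh.vertices[mesh.triangles]
    closest = _closest_points_on_triangles(p, tri)
    d2 = np.sum((closest - p) ** 2, axis=1)
    k = int(np.argmin(d2))
    return float(np.sqrt(d2[k])), closest[k]


def _closest_points_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle (vectorized Ericson scheme)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    def assign(cond, value):
        sel = cond & ~done
        out[sel] = value[sel] if value.ndim == 2 else value
        done[sel] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = d1 / (d1 - d3)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v_ab)[:, None] * ab)

    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = d2 / (d2 - d6)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(w_ac)[:, None] * ac)

    va = d3 * d6 - d5 * d4
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + np.nan_to_num(w_bc)[:, None] * (c - b))

    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    interior = a + np.nan_to_num(v)[:, None] * ab + np.nan_to_num(w)[:, None] * ac
    assign(np.ones(len(tri), dtype=bool), interior)
    return out


DEGENERATE_NORMAL_TOL = 1e-6


def plane_summary(
    mesh: DivisionMesh,
    anchor: np.ndarray,
    reference_vector: np.ndarray | None = None,
) -> PlaneMeasures:
    """Geometric summary of one division mesh.

    area = sum of triangle areas; unit_normal = normalized area-weighted
    mean of facet normals (oriented daughter 1 -> daughter 2);
    mesh_centroid = closest mesh point to the area-weighted mean of the
    triangle centroids (the center of inertia projected onto the mesh);
    anchor_distance = exact minimum distance from ``anchor`` to the mesh;
    orientation_angle = absolute angle in [0, 90] degrees between the
    normal and ``reference_vector`` (NaN when no reference is given or
    the mean normal is degenerate, e.g. for a closed surface).
    """
    anchor = np.asarray(anchor, dtype=float)
    if not np.all(np.isfinite(anchor)):
        raise ValueError("anchor must be finite")
    areas = mesh.triangle_areas
    w_normal = (areas[:, None] * mesh.triangle_normals).sum(axis=0)
    norm = np.linalg.norm(w_normal)
    degenerate = norm < DEGENERATE_NORMAL_TOL * areas.sum()
    unit_normal = np.full(3, np.nan) if degenerate else w_normal / norm
    inertia_center = (areas[:, None] * mesh.triangle_centroids).sum(axis=0) / areas.sum()
    _, mesh_centroid = point_mesh_distance(inertia_center, mesh)
    dist, _ = point_mesh_distance(anchor, mesh)
    angle = float("nan")
    if reference_vector is not None and not degenerate:
        angle = inter_plane_angle(unit_normal, np.asarray(reference_vector, float))
    return PlaneMeasures(
        area=mesh.area,
        unit_normal=unit_normal,
        mesh_centroid=mesh_centroid,
        anchor_distance=dist,
        volume_ratio=float("nan"),
        orientation_angle=angle,
        degenerate_normal=bool(degenerate),
    )


def volume_ratio(
    partition: Partition,
    selection: str = "smallest",
    selected_daughter: int | None = None,
) -> float:
    """Volume-ratio rho = V_selected / V of one division.

    ``selection="smallest"`` takes the smaller daughter (rho <= 0.5, the
    convention for symmetric-stage measurements); ``selection="by_region"``
    requires ``selected_daughter`` in {1, 2} chosen from spatial context
    (e.g. the apical or internal daughter).
    """
    v1, v2 = partition.v1, partition.v2
    if v1 == 0 or v2 == 0:
        raise ValueError("both daughters must be nonempty")
    if selection == "smallest":
        return min(v1, v2) / (v1 + v2)
    if selection == "by_region":
        if selected_daughter not in (1, 2):
            raise ValueError("by_region selection requires selected_daughter in {1, 2}")
        v = v1 if selected_daughter == 1 else v2
        return v / (v1 + v2)
    raise ValueError(f"unknown selection {selection!r}")


def inter_plane_angle(normal_a: np.ndarray, normal_b: np.ndarray) -> float:
    """Absolute angle in [0, 90] degrees between two plane normals.

    Orientation-free: antiparallel normals give 0 degrees.
    """
    na = np.asarray(normal_a, dtype=float)
    nb = np.asarray(normal_b, dtype=float)
    la, lb = np.linalg.norm(na), np.linalg.norm(nb)
    if la < 1e-12 or lb < 1e-12:
        raise ValueError("zero-length normal vector")
    cosang = abs(float(na @ nb) / (la * lb))
    return float(np.degrees(np.arccos(min(cosang, 1.0))))


def _daughter_components(partition: Partition) -> tuple[int, int]:
    grid = partition.labels_grid
    structure = ndimage.generate_binary_structure(grid.ndim, 1)
    _, n1 = ndimage.label(grid == 1, structure=structure)
    _, n2 = ndimage.label(grid == 2, structure=structure)
    return n1, n2


def measure_division(
    partition: Partition,
    anchor: np.ndarray | None = None,
    reference_vector: np.ndarray | None = None,
    selection: str = "smallest",
    selected_daughter: int | None = None,
) -> PlaneMeasures:
    """Full PlaneMeasures for one partition: mesh metrics + ratio + components."""
    if anchor is None:
        anchor = partition.mask.centroid()
    mesh = extract_interface_mesh(partition)
    pm = plane_summary(mesh, anchor, reference_vector)
    pm.volume_ratio = volume_ratio(partition, selection, selected_daughter)
    pm.n_components_d1, pm.n_components_d2 = _daughter_components(partition)
    return pm
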