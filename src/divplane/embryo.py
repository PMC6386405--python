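"""Recursive embryogenesis simulation and the embryo coordinate frame.

Starting from a single-cell mask (canonically a truncated sphere, the
shape of the embryo proper after the first asymmetric zygotic division),
the division model is run as an ensemble on every cell of every
generation; the nested centroid-then-area rule picks one solution, the
mask is split along it, and the procedure recurses. Four transitions take
the simulation from the 1-cell to the 16-cell (dermatogen) stage, with
per-transition target volume-ratios 0.5, 0.5, 0.45 and 0.33 by default
(the stage-wise ratios measured in real embryos). There is no growth
between generations: daughter masks are used as-is.

The embryo frame (i, j, k) has its origin at the centroid G1 of the first
division plane D1; i is the D1 normal, k the in-plane projection of the
direction from G1 to the suspensor centroid G2, and j = i x k. Cells are
annotated apical/central by their k-projection at the 8-cell stage
(propagated to descendants) and internal/external by |i|-projection
within each 16-cell sibling pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .division3d import ModelParams, run_ensemble
from .planes import DivisionMesh, PlaneMeasures, plane_summary
from .rules import NoAdmissibleSolutionError, select_by_nested_rule
from .shapes import CellMask

__all__ = [
    "EmbryoFrame",
    "LineageNode",
    "LineageTree",
    "build_embryo_frame",
    "annotate_cells",
    "simulate_embryogenesis",
    "DEFAULT_SCHEDULE",
]

# stage-wise target volume-ratios for the 1C->2C, 2C->4C, 4C->8C and
# 8C->16C transitions
DEFAULT_SCHEDULE = (0.5, 0.5, 0.45, 0.33)

STAGE_NAMES = {1: "1C", 2: "2C", 4: "4C", 8: "8C", 16: "16C", 32: "32C"}


@dataclass(frozen=True)
class EmbryoFrame:
    """Embryo-centered orthonormal frame with origin at G1 (um)."""

    origin: np.ndarray
    i_axis: np.ndarray
    j_axis: np.ndarray
    k_axis: np.ndarray

    def __post_init__(self) -> None:
        m = np.stack([self.i_axis, self.j_axis, self.k_axis])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if not np.allclose(np.cross(self.i_axis, self.k_axis), self.j_axis, atol=1e-9):
            raise ValueError("frame must satisfy j = i x k")

    def mirrored_k(self) -> "EmbryoFrame":
        """The frame with the apical-basal axis reversed (k -> -k)."""
        return EmbryoFrame(
            self.origin, self.i_axis, -self.j_axis, -self.k_axis
        )


def build_embryo_frame(
    d1_mesh: DivisionMesh | None,
    suspensor_centroid: np.ndarray,
    d1_normal: np.ndarray | None = None,
    d1_centroid: np.ndarray | None = None,
) -> EmbryoFrame:
    """Frame from the first division plane and the suspensor position.

    i = unit normal of D1; k = normalized projection of (G2 - G1) onto
    the plane orthogonal to i; j = i x k. Raises on the degenerate case
    where G2 - G1 is parallel to i. The plane may be given either as a
    mesh (normal and centroid measured from it) or directly as
    (d1_normal, d1_centroid).
    """
    if d1_mesh is not None:
        pm = plane_summary(d1_mesh, anchor=np.asarray(suspensor_centroid, float))
        if pm.degenerate_normal:
            raise ValueError("D1 mesh has a degenerate mean normal")
        i = pm.unit_normal
        g1 = pm.mesh_centroid
    else:
        if d1_normal is None or d1_centroid is None:
            raise ValueError("either d1_mesh or (d1_normal, d1_centroid) required")
        i = np.asarray(d1_normal, float)
        i = i / np.linalg.norm(i)
        g1 = np.asarray(d1_centroid, float)
    g2 = np.asarray(suspensor_centroid, float)
    rel = g2 - g1
    k = rel - (rel @ i) * i
    nk = np.linalg.norm(k)
    if nk < 1e-9 * max(np.linalg.norm(rel), 1.0):
        raise ValueError("degenerate frame: G2 - G1 is parallel to the D1 normal")
    k = k / nk
    j = np.cross(i, k)
    return EmbryoFrame(g1, i, j, k)


@dataclass
class LineageNode:
    """One cell in the simulated lineage."""

    name: str
    generation: int  # 1 for 1C, 2 for 2C, ...
    mask: CellMask
    parent: "LineageNode | None" = None
    children: list = field(default_factory=list)
    plane: PlaneMeasures | None = None  # the chosen division, for non-leaves
    plane_normal_frame: np.ndarray | None = None
    annotation: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LineageTree:
    root: LineageNode
    master_seed: int
    schedule: tuple

    def generation(self, g: int) -> list[LineageNode]:
        out: list[LineageNode] = []

        def walk(node: LineageNode) -> None:
            if node.generation == g:
                out.append(node)
                return
            for c in node.children:
                walk(c)

        walk(self.root)
        return sorted(out, key=lambda n: n.name)

    def leaves(self) -> list[LineageNode]:
        out = []

        def walk(node: LineageNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return sorted(out, key=lambda n: n.name)

    def to_newick(self) -> str:
        def fmt(node: LineageNode) -> str:
            tag = f"{node.name}_{STAGE_NAMES.get(2 ** (node.generation - 1), node.generation)}"
            if node.is_leaf:
                return tag
            return "(" + ",".join(fmt(c) for c in node.children) + ")" + tag

        return fmt(self.root) + ";"

    def to_dict(self) -> dict:
        def fmt(node: LineageNode) -> dict:
            d = {
                "name": node.name,
                "generation": node.generation,
                "n_sites": node.mask.n_sites,
                "volume": node.mask.volume,
                "centroid": list(map(float, node.mask.centroid())),
                "annotation": node.annotation,
            }
            if node.plane is not None:
                d["plane"] = node.plane.to_dict()
            if node.children:
                d["children"] = [fmt(c) for c in node.children]
            return d

        return {
            "master_seed": self.master_seed,
            "schedule": list(self.schedule),
            "root": fmt(self.root),
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def simulate_embryogenesis(
    initial: CellMask,
    schedule=DEFAULT_SCHEDULE,
    n_runs_per_division: int = 50,
    params: ModelParams | None = None,
    anchors: dict | None = None,
) -> LineageTree:
    """Recursively divide ``initial`` through ``len(schedule)`` transitions.

    At each cell, an ensemble of ``n_runs_per_division`` divisions is run
    at the scheduled target ratio, the nested rule (anchor = the cell's
    mask centroid, threshold = one voxel side) selects the solution, and
    the mask splits along it. If no solution is admissible the ensemble
    is re-run once with doubled size; a second failure aborts with a
    diagnostic naming the cell. Fully reproducible from ``params.seed``.

    ``anchors`` optionally maps a cell name to an externally supplied
    anchor point (um), e.g. a nucleus centroid, overriding the mask
    centroid for that cell.
    """
    if params is None:
        params = ModelParams()
    if n_runs_per_division < 1:
        raise ValueError("n_runs_per_division must be at least 1")
    schedule = tuple(schedule)
    for rho in schedule:
        if not 0 < rho < 1:
            raise ValueError("schedule ratios must lie strictly in (0, 1)")
    root = LineageNode(name="c", generation=1, mask=initial)
    frontier = [root]
    master = params.seed
    for depth, rho in enumerate(schedule):
        next_frontier = []
        for node in frontier:
            cell_seed = int(
                np.random.SeedSequence(
                    [master, depth, _name_code(node.name)]
                ).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            anchor = None
            if anchors and node.name in anchors:
                anchor = np.asarray(anchors[node.name], float)
            result = _divide_cell(node, rho, n_runs_per_division, params, cell_seed, anchor)
            node.plane = result.chosen.measures
            part = result.chosen.run.partition
            # larger daughter is child a: stable, geometry-free ordering
            order = (1, 2) if part.v1 >= part.v2 else (2, 1)
            for suffix, lbl in zip("ab", order):
                child = LineageNode(
                    name=node.name + suffix,
                    generation=node.generation + 1,
                    mask=part.daughter_mask(lbl),
                    parent=node,
                )
                node.children.append(child)
                next_frontier.append(child)
        frontier = next_frontier
    return LineageTree(root, master, schedule)


def _name_code(name: str) -> int:
    code = 0
    for ch in name:
        code = code * 3 + {"c": 0, "a": 1, "b": 2}[ch]
    return code


def _divide_cell(node, rho, n_runs, params, seed, anchor):
    mask = node.mask
    threshold = float(np.max(mask.spacing))  # one voxel side
    base = replace(params, rho_star=rho, seed=seed)
    for attempt, runs in enumerate((n_runs, 2 * n_runs)):
        results = run_ensemble(mask, base, runs, rho_mode="fixed", anchor=anchor)
        try:
            return select_by_nested_rule(results, threshold)
        except NoAdmissibleSolutionError:
            if attempt == 1:
                raise NoAdmissibleSolutionError(
                    f"cell {node.name!r} (generation {node.generation}): no "
                    f"admissible solution in {runs} runs at rho*={rho}"
                ) from None


def annotate_cells(tree: LineageTree, frame: EmbryoFrame) -> LineageTree:
    """Label cells apical/central (8C, propagated) and internal/external (16C).

    At the 8-cell generation the 4 cells with larger centroid projection
    on k are apical, the other 4 central; the label propagates to all
    descendants. Within each 16-cell sibling pair, the daughter with the
    smaller |i|-projection (closer to the first division plane) is
    internal, the other external. Ties within 1e-9 raise, as the
    annotation would be arbitrary.
    """
    eight = tree.generation(4)  # generation index 4 = 8 cells
    if len(eight) != 8:
        raise ValueError("8C generation absent or incomplete; cannot annotate")
    proj = {n.name: float((n.mask.centroid() - frame.origin) @ frame.k_axis) for n in eight}
    ordered = sorted(eight, key=lambda n: proj[n.name], reverse=True)
    if abs(proj[ordered[3].name] - proj[ordered[4].name]) < 1e-9:
        raise ValueError("ambiguous annotation: tied k-projections at 8C")
    for rank, node in enumerate(ordered):
        label = "apical" if rank < 4 else "central"
        _propagate(node, {"domain": label})
    sixteen = tree.generation(5)
    if len(sixteen) == 16:
        by_parent: dict = {}
        for n in sixteen:
            by_parent.setdefault(n.parent.name, []).append(n)
        for sibs in by_parent.values():
            pi = [
                abs(float((n.mask.centroid() - frame.origin) @ frame.i_axis))
                for n in sibs
            ]
            if abs(pi[0] - pi[1]) < 1e-9:
                raise ValueError("ambiguous annotation: tied i-projections at 16C")
            external = sibs[int(np.argmax(pi))]  # larger |i| -> external
            for n in sibs:
                n.annotation["layer"] = "external" if n is external else "internal"
    return tree


def _propagate(node: LineageNode, labels: dict) -> None:
    node.annotation.update(labels)
    for c in node.children:
        _propagate(c, labels)
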