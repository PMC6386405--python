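"""Ensemble comparison machinery and the nested centroid-then-area rule.

Solution ensembles from the stochastic division model are compared
through *relative measures*: the rank-proportion of a candidate's value
(interface area, or distance to the anchor point) within a reference set
of alternative solutions. A candidate statistically exchangeable with its
references has a relative measure uniform on [0, 1].

The nested geometrical rule selects, among the solutions passing through
or close to the anchor (distance below one voxel side), the solution of
least interface area. Orientation classes (periclinal / transverse /
anticlinal) operationalize the visual classification of planes against an
embryo coordinate frame by 30-degree cones around its reference axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .division3d import DivisionRun
from .planes import PlaneMeasures, inter_plane_angle

__all__ = [
    "RelativeMeasure",
    "Candidate",
    "NestedRuleResult",
    "NoAdmissibleSolutionError",
    "relative_measure",
    "select_by_nested_rule",
    "classify_candidate",
    "ensemble_comparison",
]


@dataclass(frozen=True)
class RelativeMeasure:
    """Proportion of reference values strictly smaller than the candidate's.

    value = |{x' in S : m(x') < m(x)}| / |S|, in [0, 1]; ties do not
    count. Invariant under any strictly increasing transform of the
    measured quantity. ``midrank=True`` instead counts ties as 1/2 (a
    sensitivity variant, not the headline definition).
    """

    value: float
    reference_set_size: int
    regime: str = "observed_rho"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("relative measure must lie in [0, 1]")
        if self.reference_set_size < 1:
            raise ValueError("reference set must be nonempty")


def relative_measure(
    x_value: float,
    reference_values: Sequence[float],
    regime: str = "observed_rho",
    midrank: bool = False,
) -> RelativeMeasure:
    refs = np.asarray(reference_values, dtype=float)
    if refs.size == 0:
        raise ValueError("reference set must be nonempty")
    below = np.count_nonzero(refs < x_value)
    if midrank:
        below = below + 0.5 * np.count_nonzero(refs == x_value)
    return RelativeMeasure(float(below) / refs.size, int(refs.size), regime)


@dataclass
class Candidate:
    """One measured solution of the division model on a mother cell."""

    run: DivisionRun
    measures: PlaneMeasures

    @property
    def rho_star(self) -> float:
        return self.run.rho_star

    @property
    def seed(self) -> int:
        return self.run.seed


def _as_candidates(candidates) -> list[Candidate]:
    out = []
    for c in candidates:
        if isinstance(c, Candidate):
            out.append(c)
        else:  # (run, measures) pair from run_ensemble
            out.append(Candidate(*c))
    return out


class NoAdmissibleSolutionError(RuntimeError):
    """No candidate passes within the distance threshold of the anchor."""


@dataclass
class NestedRuleResult:
    chosen: Candidate
    admissible: list[Candidate]
    excluded_fragmented: list[Candidate]
    excluded_distance: list[Candidate]
    threshold: float


def select_by_nested_rule(
    candidates, anchor_threshold: float
) -> NestedRuleResult:
    """Apply the centroid-then-area rule to a candidate ensemble.

    Candidates with fragmented daughters (either daughter having more
    than one connected component) are excluded first; the remainder are
    filtered to anchor_distance < ``anchor_threshold`` (one voxel side at
    the reference calibration), and the least-area survivor is chosen.
    Ties break on smaller anchor distance, then smaller seed, so the
    outcome is deterministic and independent of candidate order.

    Raises NoAdmissibleSolutionError when the filter empties the set; the
    caller may widen the ensemble and retry. Never falls back silently.
    """
    cands = _as_candidates(candidates)
    if not cands:
        raise ValueError("candidate set is empty")
    intact = [c for c in cands if not c.measures.fragmented]
    fragmented = [c for c in cands if c.measures.fragmented]
    admissible = [c for c in intact if c.measures.anchor_distance < anchor_threshold]
    too_far = [c for c in intact if c.measures.anchor_distance >= anchor_threshold]
    if not admissible:
        raise NoAdmissibleSolutionError(
            f"no solution within {anchor_threshold} of the anchor "
            f"({len(fragmented)} fragmented, {len(too_far)} too distant)"
        )
    chosen = min(
        admissible,
        key=lambda c: (c.measures.area, c.measures.anchor_distance, c.seed),
    )
    return NestedRuleResult(chosen, admissible, fragmented, too_far, anchor_threshold)


DEFAULT_CONE_DEG = 30.0


def classify_candidate(
    measures: PlaneMeasures,
    frame,
    cell_centroid: np.ndarray,
    cone_deg: float = DEFAULT_CONE_DEG,
) -> dict:
    """Orientation class and size-polarity tag of one division plane.

    The plane normal is compared against three directions derived from an
    embryo frame at the cell position: radial (from the embryo axis
    through the cell centroid, the periclinal-plane normal), axial (the
    frame's k axis, the transverse-plane normal) and tangential (their
    cross product, the normal of longitudinal anticlinal planes). The
    class is the direction whose cone (half-angle ``cone_deg``) contains
    the normal; ``other`` if none does. Polarity reports which daughter
    is larger and the sign of its centroid offset along the matched
    direction.
    """
    n = measures.unit_normal
    if measures.degenerate_normal or not np.all(np.isfinite(n)):
        return {"orientation_class": "other", "angles": {}, "polarity": None}
    cell_centroid = np.asarray(cell_centroid, float)
    axial = frame.k_axis
    rel = cell_centroid - frame.origin
    radial = rel - (rel @ axial) * axial
    if np.linalg.norm(radial) < 1e-9:
        radial = frame.i_axis
    radial = radial / np.linalg.norm(radial)
    tangential = np.cross(axial, radial)
    angles = {
        "radial": inter_plane_angle(n, radial),
        "axial": inter_plane_angle(n, axial),
        "tangential": inter_plane_angle(n, tangential),
    }
    best = min(angles, key=angles.get)
    if angles[best] >= cone_deg:
        cls = "other"
    else:
        cls = {
            "radial": "periclinal",
            "axial": "transverse",
            "tangential": "anticlinal_longitudinal",
        }[best]
    return {"orientation_class": cls, "angles": angles, "polarity": None}


def polarity_tag(partition, frame, axis: str = "k") -> dict:
    """Which daughter is larger, and where it sits along a frame axis."""
    direction = {"k": frame.k_axis, "i": frame.i_axis, "j": frame.j_axis}[axis]
    larger = 1 if partition.v1 >= partition.v2 else 2
    c1 = partition.daughter_mask(1).centroid()
    c2 = partition.daughter_mask(2).centroid()
    proj1, proj2 = c1 @ direction, c2 @ direction
    larger_proj = proj1 if larger == 1 else proj2
    smaller_proj = proj2 if larger == 1 else proj1
    return {
        "larger_daughter": larger,
        "larger_on_positive_side": bool(larger_proj > smaller_proj),
        "axis": axis,
    }


def ensemble_comparison(
    concordant,
    regimes: dict,
    quantities: tuple[str, ...] = ("area", "anchor_distance"),
) -> list[dict]:
    """Relative measures of concordant candidates against reference regimes.

    ``regimes`` maps a regime name to a reference candidate list; the
    special regime name ``random_rho_centroid_constrained`` restricts, for
    each concordant candidate, the references to those passing as close
    to the anchor as the candidate itself (anchor_distance <= its own).
    Returns long-format rows: one dict per (candidate, regime, quantity).
    Cells where a constrained regime has no qualifying reference are
    skipped with a warning.
    """
    import warnings

    rows: list[dict] = []
    concordant = _as_candidates(concordant)
    for ci, cand in enumerate(concordant):
        for regime_name, refs in regimes.items():
            refs = _as_candidates(refs)
            if regime_name == "random_rho_centroid_constrained":
                refs = [
                    r
                    for r in refs
                    if r.measures.anchor_distance <= cand.measures.anchor_distance
                ]
            if not refs:
                warnings.warn(
                    f"regime {regime_name!r}: empty reference set for "
                    f"candidate {ci}; skipped"
                )
                continue
            for q in quantities:
                rm = relative_measure(
                    getattr(cand.measures, q),
                    [getattr(r.measures, q) for r in refs],
                    regime=regime_name,
                )
                rows.append(
                    {
                        "candidate": ci,
                        "regime": regime_name,
                        "quantity": q,
                        "relative": rm.value,
                        "n_ref": rm.reference_set_size,
                        "rho_star": cand.rho_star,
                        "seed": cand.seed,
                    }
                )
    return rows
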