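"""Stochastic 3D cell-division model.

A division of a mother cell is a binary partition of its voxel mask into
two daughters. Candidate partitions are sampled by Metropolis dynamics on
the energy

    H/kT = H_V/kT + H_A/kT
    H_V/kT = ([V1 - V1*]^2 + [V2 - V2*]^2)^(1/3),   V1* = rho* V, V2* = (1 - rho*) V
    H_A/kT = alpha a^2  sum over neighbor pairs (i,j) of  1[x_i != x_j]

with the neighborhood of a voxel being its 26 nearest voxels and ``a`` the
area of one voxel facet. Discordant neighbor pairs are counted once each
(unordered pairs); the balance parameter ``alpha`` absorbs any
double-counting convention and its default of 2 is calibrated under the
once-per-pair convention. H_V vanishes exactly when the realized daughter
volumes hit the target split; H_A penalizes interface area via an
unweighted 26-direction facet count.

Each run starts from an independent random assignment and minimizes H by
single-site toggles: a uniformly random occupied site is proposed for
reassignment to the other daughter, accepted always when the energy does
not increase and with probability exp(-dH/kT) otherwise. One Monte-Carlo
cycle is N attempted toggles, N being the number of sites in the mother
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .shapes import CellMask

# facet area at the 0.35 um reference calibration; the sampler's internal
# energy scale is pinned to this so dynamics do not depend on the grid
REFERENCE_FACET_AREA = 0.35**2

__all__ = [
    "REFERENCE_FACET_AREA",
    "ModelParams",
    "Partition",
    "EnergyBreakdown",
    "DivisionRun",
    "volume_energy",
    "interface_energy",
    "delta_energy",
    "metropolis_division",
    "run_ensemble",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the division model.

    rho_star:
        Target volume-ratio of daughter 1, in (0, 1). The only free
        biological parameter of the model.
    alpha:
        Weight balancing interface area against the volume constraint
        (default 2; too low fragments the partition, too high collapses
        one daughter).
    facet_area:
        Area ``a`` of one voxel facet entering H_A. ``None`` (default)
        uses the reference value 0.35^2 um^2 (the facet area at the
        0.35 um resampled acquisition calibration), *independent of the
        mask calibration*: because H_V counts voxels, the dynamics depend
        on the absolute magnitudes of both terms relative to kT, and
        fixing a makes runs behave identically on every grid. Physical
        interface areas are always measured on the extracted mesh, never
        through ``a``.
    kT:
        Energy scale of the Metropolis acceptance rule. ``None`` (default)
        sets kT = alpha * a^2 (one voxel facet of interface energy,
        = 0.030 with the defaults above). This is the regime in which
        alpha = 2 yields clean minimal interfaces at exact target ratios:
        the interface term is of order kT per facet while the voxel-count
        volume term is tens of kT per voxel, pinning the ratio without
        freezing the interface (see the methods note). Raising kT to
        order 1 lets asymmetric runs collapse into a single daughter.
    n_cycles:
        Monte-Carlo cycles (N attempted toggles each). 5000 cycles reach
        convergence on cell-sized masks.
    init:
        ``"bernoulli_half"`` (default) assigns each site to either
        daughter with probability 1/2; ``"bernoulli_rho"`` uses
        probability rho_star for daughter 1. The symmetric start is more
        robust for asymmetric targets: beginning at the target ratio
        leaves the minority daughter dispersed as isolated sites, which
        occasionally evaporate wholesale before compact domains form
        (a few percent of runs collapse into a single daughter); from a
        half/half start the excess volume must be shed through the
        volume term, by which time the surviving daughter is compact.
    target_snap:
        ``"half_integer"`` (default) snaps the sampler's internal target
        volume V1* to the nearest half-integer voxel count (a shift of at
        most half a voxel, i.e. a ratio error below 1/N). On a lattice
        the energy H_V has a cusp at the target; when rho_star*N is an
        integer that cusp freezes every single-site toggle, an artifact
        of the discretization rather than a feature of the model.
        ``"exact"`` uses rho_star*N verbatim.
    early_stop:
        If true, stop once the ``early_stop_window``-cycle moving average
        of H changes by less than ``early_stop_rtol`` (relative).
    """

    rho_star: float = 0.5
    alpha: float = 2.0
    facet_area: float | None = None
    kT: float | None = None
    n_cycles: int = 5000
    seed: int = 0
    init: str = "bernoulli_half"
    target_snap: str = "half_integer"
    early_stop: bool = False
    early_stop_window: int = 100
    early_stop_rtol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.rho_star < 1:
            raise ValueError("rho_star must lie strictly between 0 and 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.facet_area is not None and self.facet_area <= 0:
            raise ValueError("facet_area must be positive")
        if self.kT is not None and self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if self.init not in ("bernoulli_rho", "bernoulli_half"):
            raise ValueError(f"unknown init scheme {self.init!r}")
        if self.target_snap not in ("half_integer", "exact"):
            raise ValueError(f"unknown target_snap {self.target_snap!r}")

    def resolve(self, mask: CellMask | None = None) -> "ModelParams":
        """Fill the default sampler scales (facet area, kT)."""
        a = self.facet_area
        if a is None:
            a = REFERENCE_FACET_AREA
        kT = self.kT
        if kT is None:
            kT = self.alpha * a**2
        return replace(self, facet_area=a, kT=kT)

    @property
    def alpha_a2(self) -> float:
        if self.facet_area is None:
            raise ValueError("facet_area unresolved; call params.resolve(mask)")
        return self.alpha * self.facet_area**2

    def sampler_targets(self, n_sites: int) -> tuple[float, float]:
        """Internal target volumes (V1*, V2*) used by the sampler."""
        t1 = self.rho_star * n_sites
        if self.target_snap == "half_integer":
            t1 = np.floor(t1) + 0.5
        return float(t1), float(n_sites - t1)


@dataclass
class Partition:
    """Assignment of every mother-cell site to daughter 1 or daughter 2.

    ``labels`` has the mother grid shape, with 0 outside the mask and 1/2
    on occupied sites. ``site_labels`` is the flat per-site view in the
    canonical site enumeration (argwhere order).
    """

    mask: CellMask
    site_labels: np.ndarray
    site_indices: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    nbr_ptr: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    nbr_idx: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.site_labels = np.asarray(self.site_labels, dtype=np.int8)
        if self.site_indices is None:
            self.site_indices, self.nbr_ptr, self.nbr_idx = _kernels.build_adjacency(
                self.mask.occupancy
            )
        if self.site_labels.shape != (self.mask.n_sites,):
            raise ValueError("one label per occupied site required")
        if not np.all((self.site_labels == 1) | (self.site_labels == 2)):
            raise ValueError("labels must be 1 or 2")

    @classmethod
    def from_labels_grid(cls, mask: CellMask, labels_grid: np.ndarray) -> "Partition":
        occ = mask.occupancy
        return cls(mask, np.asarray(labels_grid)[occ].astype(np.int8))

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

    def daughter_mask(self, which: int) -> CellMask:
        """The daughter cell (1 or 2) as a CellMask on the mother grid."""
        if which not in (1, 2):
            raise ValueError("daughter label must be 1 or 2")
        occ = np.zeros(self.mask.occupancy.shape, dtype=bool)
        sel = self.site_labels == which
        occ[tuple(self.site_indices[sel].T)] = True
        return CellMask(occ, self.mask.calibration, self.mask.origin_offset.copy())

    def relabeled(self) -> "Partition":
        """Swap daughters 1 and 2."""
        return Partition(
            self.mask,
            (3 - self.site_labels).astype(np.int8),
            self.site_indices,
            self.nbr_ptr,
            self.nbr_idx,
        )


@dataclass(frozen=True)
class EnergyBreakdown:
    h_v: float
    h_a: float
    delta: float = 0.0

    @property
    def h_total(self) -> float:
        return self.h_v + self.h_a


def volume_energy(partition: Partition, params: ModelParams) -> float:
    """H_V/kT = ([V1 - V1*]^2 + [V2 - V2*]^2)^(1/3), targets from rho*."""
    n = partition.n_sites
    v1_target = params.rho_star * n
    v2_target = (1.0 - params.rho_star) * n
    d1 = partition.v1 - v1_target
    d2 = partition.v2 - v2_target
    return float((d1 * d1 + d2 * d2) ** (1.0 / 3.0))


def interface_energy(partition: Partition, params: ModelParams) -> float:
    """H_A/kT = alpha a^2 x (number of discordant unordered neighbor pairs)."""
    params = params.resolve(partition.mask)
    pairs = _kernels.discordant_pairs(
        partition.site_labels, partition.nbr_ptr, partition.nbr_idx
    )
    return params.alpha_a2 * pairs


def total_energy(partition: Partition, params: ModelParams) -> EnergyBreakdown:
    params = params.resolve(partition.mask)
    return EnergyBreakdown(
        volume_energy(partition, params), interface_energy(partition, params)
    )


def delta_energy(partition: Partition, site, params: ModelParams) -> float:
    """Energy change dH from toggling one site to the other daughter.

    ``site`` is a grid index tuple of an occupied mother-cell site. Only
    the site's (at most 26) neighbor facets and the two daughter volume
    counts enter the computation.
    """
    params = params.resolve(partition.mask)
    site = tuple(int(s) for s in np.atleast_1d(site))
    if not partition.mask.occupancy[site]:
        raise ValueError(f"site {site} is outside the mother mask")
    flat = np.flatnonzero(np.all(partition.site_indices == site, axis=1))
    i = int(flat[0])
    labels = partition.site_labels
    li = labels[i]
    nbrs = partition.nbr_idx[partition.nbr_ptr[i] : partition.nbr_ptr[i + 1]]
    m = nbrs.size
    d = int(np.count_nonzero(labels[nbrs] != li))
    d_ha = params.alpha_a2 * (m - 2 * d)
    n = partition.n_sites
    v1_target = params.rho_star * n
    v2_target = (1.0 - params.rho_star) * n
    v1_new = partition.v1 + (-1 if li == 1 else 1)

    def hv(v1):
        return ((v1 - v1_target) ** 2 + ((n - v1) - v2_target) ** 2) ** (1.0 / 3.0)

    return float(d_ha + hv(v1_new) - hv(partition.v1))


@dataclass
class DivisionRun:
    """One completed Metropolis run on a mother cell."""

    partition: Partition
    energy: EnergyBreakdown
    trace: np.ndarray
    rho_star: float
    seed: int

    @property
    def realized_ratio(self) -> float:
        return self.partition.v1 / self.partition.n_sites


def _initial_labels(n: int, params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    p = params.rho_star if params.init == "bernoulli_rho" else 0.5
    return np.where(rng.random(n) < p, 1, 2).astype(np.int8)


def metropolis_division(mask: CellMask, params: ModelParams) -> DivisionRun:
    """Run one stochastic division of ``mask`` under ``params``.

    Fully reproducible: the initial assignment and the toggle dynamics are
    both driven by ``params.seed``.
    """
    if mask.ndim != 3:
        raise ValueError("metropolis_division expects a 3D mask; see division2d")
    params = params.resolve(mask)
    site_indices, nbr_ptr, nbr_idx = _kernels.build_adjacency(mask.occupancy)
    n = site_indices.shape[0]
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    labels = _initial_labels(n, params, rng)
    kernel_seed = int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
    v1_target, v2_target = params.sampler_targets(n)
    v1, bpairs, trace, _ = _kernels.metropolis_toggle(
        labels,
        nbr_ptr,
        nbr_idx,
        v1_target,
        v2_target,
        params.alpha_a2,
        params.kT,
        params.n_cycles,
        kernel_seed,
        params.early_stop,
        params.early_stop_window,
        params.early_stop_rtol,
    )
    part = Partition(mask, labels, site_indices, nbr_ptr, nbr_idx)
    assert part.v1 == v1  # kernel bookkeeping must agree with recount
    energy = EnergyBreakdown(volume_energy(part, params), params.alpha_a2 * bpairs)
    return DivisionRun(part, energy, trace, params.rho_star, params.seed)


def run_ensemble(
    mask: CellMask,
    base_params: ModelParams,
    n_runs: int,
    rho_mode: str = "fixed",
    rho_range: tuple[float, float] = (0.2, 0.5),
    measure: bool = True,
    anchor: np.ndarray | None = None,
) -> list:
    """Run the division model ``n_runs`` times on one mother cell.

    rho_mode ``"fixed"`` reuses ``base_params.rho_star`` for every run;
    ``"uniform_random"`` draws each run's target ratio uniformly from
    ``rho_range`` (the regime used to explore the solution space across
    volume-ratios). Each run gets an independent substream derived from
    (base seed, run index), so the ensemble is reproducible and
    order-independent. When ``measure`` is true each run is paired with
    its PlaneMeasures against ``anchor`` (default: mother centroid).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    if rho_mode not in ("fixed", "uniform_random"):
        raise ValueError(f"unknown rho_mode {rho_mode!r}")
    lo, hi = rho_range
    if rho_mode == "uniform_random" and not 0 < lo < hi < 1:
        raise ValueError("rho_range must satisfy 0 < low < high < 1")
    if measure:
        from .planes import measure_division

        if anchor is None:
            anchor = mask.centroid()
    results = []
    for k in range(n_runs):
        sub_seed = int(
            np.random.SeedSequence([base_params.seed, k]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        if rho_mode == "uniform_random":
            rho = float(np.random.default_rng(sub_seed).uniform(lo, hi))
        else:
            rho = base_params.rho_star
        params = replace(base_params, rho_star=rho, seed=sub_seed)
        run = metropolis_division(mask, params)
        if measure:
            measures = measure_division(run.partition, anchor=anchor)
            results.append((run, measures))
        else:
            results.append(run)
    return results
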