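"""Energy terms, local updates, and the 3D Metropolis sampler."""

import numpy as np
import pytest

from divplane.division3d import (
    ModelParams,
    Partition,
    delta_energy,
    interface_energy,
    metropolis_division,
    run_ensemble,
    total_energy,
    volume_energy,
)
from divplane.shapes import CellMask, digitize_shape

from conftest import random_partition

LATTICE = ModelParams(facet_area=1.0, kT=1.0)  # a = 1, unit-side grids


def brute_force_discordant_pairs(partition: Partition) -> int:
    """Exhaustive enumeration over all unordered 26-neighbor pairs."""
    grid = partition.labels_grid
    occ = partition.mask.occupancy
    idx = np.argwhere(occ)
    count = 0
    offsets = [
        np.array(o)
        for o in np.ndindex(3, 3, 3)
        if o != (1, 1, 1)
    ]
    for p in idx:
        for off in offsets:
            q = p + off - 1
            if np.any(q < 0) or np.any(q >= np.array(occ.shape)):
                continue
            if occ[tuple(q)] and tuple(q) > tuple(p):
                if grid[tuple(p)] != grid[tuple(q)]:
                    count += 1
    return count


class TestVolumeEnergy:
    @pytest.mark.parametrize(
        "n,rho,v1,expected",
        [
            (1000, 0.5, 500, 0.0),
            (1000, 0.5, 400, 20000.0 ** (1.0 / 3.0)),  # = 27.144...
            (1000, 0.3, 300, 0.0),
        ],
    )
    def test_cube_root_form(self, unit_cal, n, rho, v1, expected):
        occ = np.zeros((10, 10, 10), bool)
        occ.ravel()[:n] = True
        mask = CellMask(occ, unit_cal)
        labels = np.full(n, 2, dtype=np.int8)
        labels[:v1] = 1
        part = Partition(mask, labels)
        params = ModelParams(rho_star=rho, facet_area=1.0, kT=1.0)
        assert volume_energy(part, params) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_zero_only_at_target(self, cube6):
        params = ModelParams(rho_star=0.25, facet_area=1.0, kT=1.0)
        n = cube6.n_sites  # 216; target v1 = 54
        for v1 in (1, 53, 54, 55, 215):
            labels = np.full(n, 2, dtype=np.int8)
            labels[:v1] = 1
            e = volume_energy(Partition(cube6, labels), params)
            assert e >= 0
            assert (e == 0) == (v1 == 54)


class TestInterfaceEnergy:
    def test_two_voxel_mask_single_pair(self, unit_cal):
        occ = np.zeros((5, 5, 5), bool)
        occ[2, 2, 2:4] = True
        mask = CellMask(occ, unit_cal)
        part = Partition(mask, np.array([1, 2], dtype=np.int8))
        assert interface_energy(part, LATTICE) == pytest.approx(2.0)

    def test_uniform_partition_has_zero_interface(self, cube6):
        part = Partition(cube6, np.ones(cube6.n_sites, dtype=np.int8))
        assert interface_energy(part, LATTICE) == 0.0

    def test_flat_split_cube_matches_exhaustive_enumeration(self, unit_cal):
        occ = np.zeros((7, 7, 7), bool)
        occ[2:5, 2:5, 2:5] = True  # 3x3x3 solid cube
        mask = CellMask(occ, unit_cal)
        idx = np.argwhere(occ)
        labels = np.where(idx[:, 2] == 2, 1, 2).astype(np.int8)  # 9 vs 18
        part = Partition(mask, labels)
        expected = brute_force_discordant_pairs(part)
        assert interface_energy(part, LATTICE) == pytest.approx(2.0 * expected)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_partitions_match_exhaustive_enumeration(self, cube6, seed):
        part = random_partition(cube6, seed)
        expected = brute_force_discordant_pairs(part)
        assert interface_energy(part, LATTICE) == pytest.approx(2.0 * expected)

    def test_relabeling_daughters_leaves_energy_unchanged(self, cube6):
        part = random_partition(cube6, 3)
        params = ModelParams(rho_star=0.5, facet_area=1.0, kT=1.0)
        assert interface_energy(part, params) == interface_energy(
            part.relabeled(), params
        )
        assert volume_energy(part, params) == pytest.approx(
            volume_energy(part.relabeled(), params)
        )


class TestDeltaEnergy:
    def test_interior_site_all_same_label(self, cube6):
        labels = np.ones(cube6.n_sites, dtype=np.int8)
        labels[0] = 2  # keep both daughters nonempty
        part = Partition(cube6, labels)
        params = ModelParams(rho_star=0.5, facet_area=1.0, kT=1.0)
        site = (4, 4, 4)  # interior: 26 same-label neighbors
        d = delta_energy(part, site, params)
        before = total_energy(part, params)
        after = _toggled(part, site)
        expected = total_energy(after, params).h_total - before.h_total
        assert d == pytest.approx(expected, abs=1e-9)
        # the area part alone is alpha a^2 * 26 = 52
        assert d - (
            volume_energy(after, params) - volume_energy(part, params)
        ) == pytest.approx(52.0)

    def test_toggle_involution_sums_to_zero(self, cube6):
        part = random_partition(cube6, 7)
        params = ModelParams(rho_star=0.4, facet_area=1.0, kT=1.0)
        site = (3, 5, 2)
        d1 = delta_energy(part, site, params)
        toggled = _toggled(part, site)
        d2 = delta_energy(toggled, site, params)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)

    def test_hundred_random_toggles_match_global_recompute(self, cube6):
        """Local update vs full recompute: the oracle-equivalence contract."""
        rng = np.random.default_rng(11)
        part = random_partition(cube6, 11)
        params = ModelParams(rho_star=0.33, facet_area=1.0, kT=1.0)
        sites = part.site_indices
        for _ in range(100):
            site = tuple(sites[rng.integers(len(sites))])
            d = delta_energy(part, site, params)
            before = total_energy(part, params).h_total
            part = _toggled(part, site)
            after = total_energy(part, params).h_total
            assert d == pytest.approx(after - before, abs=1e-9)

    def test_site_outside_mask_rejected(self, cube6):
        part = random_partition(cube6, 0)
        with pytest.raises(ValueError, match="outside"):
            delta_energy(part, (0, 0, 0), ModelParams(facet_area=1.0, kT=1.0))


def _toggled(part: Partition, site) -> Partition:
    i = int(np.flatnonzero(np.all(part.site_indices == site, axis=1))[0])
    labels = part.site_labels.copy()
    labels[i] = 3 - labels[i]
    return Partition(part.mask, labels, part.site_indices, part.nbr_ptr, part.nbr_idx)


def reference_metropolis(mask, params, record):
    """Instrumented pure-python Metropolis, used as the dynamics oracle.

    Follows the published acceptance rule literally and records every
    proposed move as (dH, accepted); independent of the compiled kernel.
    """
    from divplane.division3d import _initial_labels

    params = params.resolve(mask)
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    labels = _initial_labels(mask.n_sites, params, rng)
    part = Partition(mask, labels)
    t1, t2 = params.sampler_targets(part.n_sites)
    v1 = part.v1
    move_rng = np.random.default_rng(123)
    grid_labels = part.site_labels
    n = part.n_sites

    def hv(v):
        return ((v - t1) ** 2 + ((n - v) - t2) ** 2) ** (1.0 / 3.0)

    for _ in range(params.n_cycles * n):
        i = int(move_rng.integers(n))
        li = grid_labels[i]
        nbrs = part.nbr_idx[part.nbr_ptr[i] : part.nbr_ptr[i + 1]]
        m = nbrs.size
        d = int(np.count_nonzero(grid_labels[nbrs] != li))
        dv = -1 if li == 1 else 1
        dH = params.alpha_a2 * (m - 2 * d) + hv(v1 + dv) - hv(v1)
        accept = dH <= 0.0 or move_rng.random() < np.exp(-dH / params.kT)
        record.append((dH, accept, v1 + (dv if accept else 0)))
        if accept:
            grid_labels[i] = 3 - li
            v1 += dv
    return Partition(mask, grid_labels), v1


class TestMetropolisDynamics:
    def test_acceptance_rule_and_conservation_on_instrumented_run(self, unit_cal):
        """Every dH <= 0 move accepted; v1 + v2 = N after every move."""
        mask = digitize_shape("sphere", 4.0, unit_cal)
        record = []
        part, v1 = reference_metropolis(
            mask, ModelParams(rho_star=0.4, n_cycles=3, seed=5), record
        )
        assert len(record) == 3 * mask.n_sites
        downhill = [(dH, acc) for dH, acc, _ in record if dH <= 0]
        assert downhill and all(acc for _, acc in downhill)
        # v1 recorded after each move stays within [0, N]: conservation
        assert all(0 <= v <= mask.n_sites for _, _, v in record)
        assert part.v1 + part.v2 == mask.n_sites == v1 + part.v2

    def test_kernel_reaches_same_regime_as_reference(self, unit_cal):
        """Compiled kernel vs pure-python oracle on a small sphere."""
        mask = digitize_shape("sphere", 4.5, unit_cal)
        params = ModelParams(rho_star=0.5, n_cycles=300, seed=9)
        record = []
        ref_part, _ = reference_metropolis(mask, params, record)
        run = metropolis_division(mask, params)
        ref_e = total_energy(ref_part, params.resolve(mask)).h_total
        kern_e = run.energy.h_total
        # independent RNG streams: same equilibrium, not the same configuration
        assert abs(run.realized_ratio - 0.5) < 0.05
        assert kern_e == pytest.approx(ref_e, rel=0.25)

    def test_determinism_identical_seeds(self, unit_cal):
        mask = digitize_shape("sphere", 5.0, unit_cal)
        p = ModelParams(rho_star=0.4, n_cycles=100, seed=21)
        r1 = metropolis_division(mask, p)
        r2 = metropolis_division(mask, p)
        assert np.array_equal(r1.partition.site_labels, r2.partition.site_labels)
        assert np.array_equal(r1.trace, r2.trace)

    def test_energy_breakdown_consistency(self, unit_cal):
        mask = digitize_shape("sphere", 5.0, unit_cal)
        run = metropolis_division(mask, ModelParams(n_cycles=50, seed=2))
        params = ModelParams(n_cycles=50, seed=2).resolve(mask)
        assert run.energy.h_a == pytest.approx(interface_energy(run.partition, params))
        assert run.energy.h_total == run.energy.h_v + run.energy.h_a

    def test_median_energy_trace_nonincreasing_after_burnin(self, unit_cal):
        mask = digitize_shape("sphere", 6.0, unit_cal)
        traces = []
        for seed in range(4):
            run = metropolis_division(
                mask, ModelParams(rho_star=0.5, n_cycles=400, seed=seed)
            )
            traces.append(run.trace)
        med = np.median(np.stack(traces), axis=0)
        burn = len(med) // 10
        smoothed = np.convolve(med[burn:], np.ones(25) / 25, mode="valid")
        assert np.all(np.diff(smoothed) <= 1e-6 + 0.02 * np.abs(smoothed[:-1]))


class TestRunEnsemble:
    def test_fixed_mode_reports_base_rho(self, unit_cal):
        mask = digitize_shape("sphere", 4.0, unit_cal)
        runs = run_ensemble(
            mask, ModelParams(rho_star=0.37, n_cycles=20, seed=1), 5,
            rho_mode="fixed", measure=False,
        )
        assert [r.rho_star for r in runs] == [0.37] * 5

    def test_uniform_random_rho_mean(self, unit_cal):
        mask = digitize_shape("sphere", 4.0, unit_cal)
        runs = run_ensemble(
            mask, ModelParams(n_cycles=1, seed=3), 200,
            rho_mode="uniform_random", rho_range=(0.2, 0.5), measure=False,
        )
        rhos = np.array([r.rho_star for r in runs])
        assert np.all((rhos > 0.2) & (rhos < 0.5))
        assert abs(rhos.mean() - 0.35) < 0.03

    def test_runs_reproducible_from_recorded_substream_seed(self, unit_cal):
        mask = digitize_shape("sphere", 4.0, unit_cal)
        base = ModelParams(rho_star=0.4, n_cycles=30, seed=17)
        runs = run_ensemble(mask, base, 3, measure=False)
        for r in runs:
            replay = metropolis_division(
                mask, ModelParams(rho_star=r.rho_star, n_cycles=30, seed=r.seed)
            )
            assert np.array_equal(replay.partition.site_labels, r.partition.site_labels)

    def test_invalid_modes_rejected(self, unit_cal):
        mask = digitize_shape("sphere", 4.0, unit_cal)
        with pytest.raises(ValueError):
            run_ensemble(mask, ModelParams(), 0)
        with pytest.raises(ValueError):
            run_ensemble(mask, ModelParams(), 1, rho_mode="gaussian")
        with pytest.raises(ValueError):
            run_ensemble(mask, ModelParams(), 1, rho_mode="uniform_random", rho_range=(0.5, 0.2))


class TestModelParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho_star": 0.0},
            {"rho_star": 1.2},
            {"alpha": -1.0},
            {"facet_area": 0.0},
            {"n_cycles": 0},
            {"init": "plane"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_resolve_fills_reference_scales(self):
        p = ModelParams().resolve()
        assert p.facet_area == pytest.approx(0.35**2)
        assert p.kT == pytest.approx(2.0 * 0.35**4)

    def test_half_integer_target_snap(self):
        p = ModelParams(rho_star=0.5)
        t1, t2 = p.sampler_targets(1000)
        assert t1 == 500.5 and t1 + t2 == 1000
        exact = ModelParams(rho_star=0.5, target_snap="exact")
        assert exact.sampler_targets(1000)[0] == 500.0
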