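"""Relative measures, the nested selection rule, and ensemble comparison."""

import numpy as np
import pytest
from scipy import stats

from divplane.planes import PlaneMeasures
from divplane.rules import (
    Candidate,
    NoAdmissibleSolutionError,
    ensemble_comparison,
    relative_measure,
    select_by_nested_rule,
)


def fake_candidate(area, dist, seed=0, rho=0.4, comps=(1, 1)):
    """Candidate with synthetic measures (no simulation behind it)."""

    class _Run:
        rho_star = rho

        def __init__(self, s):
            self.seed = s

    pm = PlaneMeasures(
        area=area,
        unit_normal=np.array([0.0, 0.0, 1.0]),
        mesh_centroid=np.zeros(3),
        anchor_distance=dist,
        volume_ratio=rho,
        n_components_d1=comps[0],
        n_components_d2=comps[1],
    )
    return Candidate(_Run(seed), pm)


class TestRelativeMeasure:
    def test_smaller_than_all_references(self):
        assert relative_measure(0.5, list(range(1, 11))).value == 0.0

    def test_larger_than_all_references(self):
        assert relative_measure(99.0, list(range(1, 11))).value == 1.0

    def test_direct_count(self):
        assert relative_measure(2.5, [1, 2, 3, 4]).value == 0.5

    def test_strict_inequality_ignores_ties(self):
        assert relative_measure(2.0, [1, 2, 2, 3]).value == 0.25
        assert relative_measure(2.0, [1, 2, 2, 3], midrank=True).value == 0.5

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            relative_measure(1.0, [])

    def test_single_reference_is_binary(self):
        assert relative_measure(5.0, [3.0]).value == 1.0
        assert relative_measure(1.0, [3.0]).value == 0.0

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        refs = rng.exponential(size=30)
        x = float(rng.exponential())
        base = relative_measure(x, refs).value
        for f in (np.log, np.sqrt, lambda v: 3 * v + 1):
            assert relative_measure(f(x), f(refs)).value == base

    def test_null_distribution_uniform_on_grid(self):
        """Exchangeable candidate => value uniform on {0, 1/|S|, ..., 1}."""
        rng = np.random.default_rng(7)
        n_ref = 19
        vals = []
        for _ in range(2000):
            pool = rng.normal(size=n_ref + 1)
            vals.append(relative_measure(pool[0], pool[1:]).value)
        counts = np.bincount((np.array(vals) * n_ref).round().astype(int), minlength=n_ref + 1)
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=n_ref)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestRelativeMeasureProperties:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        x=st.floats(-1e6, 1e6),
        refs=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
    )
    def test_bounds_and_rank_semantics(self, x, refs):
        rm = relative_measure(x, refs)
        assert 0.0 <= rm.value <= 1.0
        assert rm.value * len(refs) == pytest.approx(
            sum(r < x for r in refs), abs=1e-9
        )
        # doubling is an exactly order-preserving float transform
        assert relative_measure(2 * x, [2 * r for r in refs]).value == rm.value


class TestNestedRule:
    def test_single_close_candidate_chosen(self):
        c = fake_candidate(30.0, 0.2)
        res = select_by_nested_rule([c], anchor_threshold=1.0)
        assert res.chosen is c

    def test_least_area_governs_among_admissible(self):
        a = fake_candidate(30.0, 0.5, seed=1)
        b = fake_candidate(40.0, 0.4, seed=2)
        res = select_by_nested_rule([a, b], anchor_threshold=1.0)
        assert res.chosen is a
        assert len(res.admissible) == 2

    def test_all_too_distant_raises(self):
        cands = [fake_candidate(10.0, 1.0), fake_candidate(12.0, 2.5)]
        with pytest.raises(NoAdmissibleSolutionError):
            select_by_nested_rule(cands, anchor_threshold=1.0)

    def test_fragmented_candidates_excluded_before_filtering(self):
        frag = fake_candidate(5.0, 0.1, seed=1, comps=(2, 1))  # would win otherwise
        ok = fake_candidate(30.0, 0.5, seed=2)
        res = select_by_nested_rule([frag, ok], anchor_threshold=1.0)
        assert res.chosen is ok
        assert res.excluded_fragmented == [frag]

    def test_order_invariance_and_deterministic_ties(self):
        cands = [
            fake_candidate(30.0, 0.5, seed=3),
            fake_candidate(30.0, 0.5, seed=1),
            fake_candidate(30.0, 0.3, seed=2),
        ]
        first = select_by_nested_rule(cands, 1.0).chosen
        for perm in ([1, 2, 0], [2, 0, 1], [2, 1, 0]):
            again = select_by_nested_rule([cands[i] for i in perm], 1.0).chosen
            assert again is first
        assert first.measures.anchor_distance == 0.3  # distance tiebreak

    def test_audit_record_lists_reasons(self):
        frag = fake_candidate(5.0, 0.1, comps=(1, 3))
        far = fake_candidate(8.0, 3.0)
        ok = fake_candidate(30.0, 0.5)
        res = select_by_nested_rule([frag, far, ok], 1.0)
        assert res.excluded_fragmented == [frag]
        assert res.excluded_distance == [far]
        assert res.threshold == 1.0


class TestEnsembleComparison:
    def test_concordant_smaller_than_all_constrained_references(self):
        conc = fake_candidate(10.0, 0.3)
        refs = [fake_candidate(20.0 + i, 0.05 + 0.1 * i) for i in range(5)]
        rows = ensemble_comparison(
            [conc], {"random_rho_centroid_constrained": refs}
        )
        area_rows = [r for r in rows if r["quantity"] == "area"]
        assert len(area_rows) == 1
        assert area_rows[0]["relative"] == 0.0
        # constrained regime keeps only refs at distance <= 0.3
        assert area_rows[0]["n_ref"] == 3

    def test_empty_constrained_regime_skipped_with_warning(self):
        conc = fake_candidate(10.0, 0.05)
        refs = [fake_candidate(20.0, 0.5)]
        with pytest.warns(UserWarning, match="empty reference"):
            rows = ensemble_comparison(
                [conc], {"random_rho_centroid_constrained": refs}
            )
        assert rows == []

    def test_self_comparison_uniformity_ks(self):
        """Â drawn from the same distribution as its references is uniform:
        KS vs U(0,1) below the 5% critical value in >= 90% of repetitions."""
        rng = np.random.default_rng(42)
        n_rep, n_ref = 50, 60
        passes = 0
        for _ in range(n_rep):
            vals = []
            for _ in range(40):
                pool = rng.normal(size=n_ref + 1)
                vals.append(relative_measure(pool[0], pool[1:]).value)
            stat = stats.kstest(vals, "uniform").statistic
            crit = 1.358 / np.sqrt(len(vals))  # asymptotic 5% KS critical value
            passes += stat < crit
        assert passes >= 0.9 * n_rep


class TestClassifyCandidate:
    @staticmethod
    def _frame():
        from divplane.embryo import EmbryoFrame

        i = np.array([1.0, 0.0, 0.0])
        k = np.array([0.0, 0.0, 1.0])
        return EmbryoFrame(np.zeros(3), i, np.cross(i, k), k)

    @staticmethod
    def _measures(normal):
        return PlaneMeasures(
            area=10.0,
            unit_normal=np.asarray(normal, float),
            mesh_centroid=np.zeros(3),
            anchor_distance=0.1,
            volume_ratio=0.4,
        )

    @pytest.mark.parametrize(
        "normal,expected",
        [
            ([0, 1, 0], "periclinal"),  # along the radial direction
            ([0, 0, 1], "transverse"),  # along the embryo axis k
            ([1, 0, 0], "anticlinal_longitudinal"),  # tangential
        ],
    )
    def test_cone_classification(self, normal, expected):
        from divplane.rules import classify_candidate

        out = classify_candidate(
            self._measures(normal), self._frame(), cell_centroid=[0.0, 3.0, 0.0]
        )
        assert out["orientation_class"] == expected

    def test_between_cones_is_other(self):
        from divplane.rules import classify_candidate

        n = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)  # 45 deg to radial and axial
        out = classify_candidate(
            self._measures(n), self._frame(), cell_centroid=[0.0, 3.0, 0.0]
        )
        assert out["orientation_class"] == "other"

    def test_degenerate_normal_is_other(self):
        from divplane.rules import classify_candidate

        pm = self._measures([0, 1, 0])
        pm.degenerate_normal = True
        out = classify_candidate(pm, self._frame(), cell_centroid=[0.0, 3.0, 0.0])
        assert out["orientation_class"] == "other"
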