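"""Wilcoxon rank-sum, Holm adjustment and cohort comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from h2profile import (
    CohortTable,
    compare_cohorts,
    family_ratio,
    holm_adjust,
    wilcoxon_rank_sum,
)

from conftest import exact_two_sided_p


class TestWilcoxonExact:
    def test_two_vs_two_extreme_split(self):
        w, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert w == 3
        assert p == pytest.approx(1 / 3)

    def test_three_vs_three_extreme_split(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 6
        assert p == pytest.approx(0.1)

    def test_all_tie_free_splits_match_counting_oracle(self):
        """Exact p equals the full-enumeration null for every split with
        combined n <= 10."""
        for n_total in range(4, 11):
            values = np.arange(1.0, n_total + 1)
            for m in range(1, n_total):
                for comb in itertools.combinations(values, m):
                    x = np.array(comb)
                    y = np.array(sorted(set(values) - set(comb)))
                    w, p = wilcoxon_rank_sum(x, y, mode="exact")
                    assert p == pytest.approx(exact_two_sided_p(w, m, n_total - m))

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_ties_refused_in_exact_mode(self):
        with pytest.raises(ValueError, match="tie"):
            wilcoxon_rank_sum([1, 1], [2, 3], mode="exact")


class TestWilcoxonNormal:
    def test_constant_data_p_one(self):
        _, p = wilcoxon_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0], mode="normal")
        assert p == 1.0

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(1.0, 1.0, size=11)
            _, pxy = wilcoxon_rank_sum(x, y, mode="normal")
            _, pyx = wilcoxon_rank_sum(y, x, mode="normal")
            assert pxy == pytest.approx(pyx, abs=1e-12)
            _, exy = wilcoxon_rank_sum(x[:4], y[:5], mode="exact")
            _, eyx = wilcoxon_rank_sum(y[:5], x[:4], mode="exact")
            assert exy == pytest.approx(eyx, abs=1e-12)

    def test_close_to_exact_for_moderate_groups(self):
        """Continuity-corrected normal p within 0.02 of exact for tie-free
        data with 6-12 samples per group (spot sample of splits)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            m, n = rng.integers(6, 13, size=2)
            pooled = rng.permutation(np.arange(1.0, m + n + 1))
            x, y = pooled[:m], pooled[m:]
            w, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
            assert abs(p_norm - exact_two_sided_p(w, m, n)) <= 0.02

    def test_tie_corrected_variance_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 4, size=15).astype(float)
            y = rng.integers(0, 4, size=18).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            _, p = wilcoxon_rank_sum(x, y, mode="normal")
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p == pytest.approx(ref, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestHolm:
    def test_two_value_worked_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_value_unchanged(self):
        assert holm_adjust([0.5]) == [0.5]

    def test_equal_values_monotone_cummax(self):
        assert holm_adjust([0.03, 0.03, 0.03]) == pytest.approx([0.09, 0.09, 0.09])

    def test_bounds_and_order_preservation(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20)
        adj = np.array(holm_adjust(p))
        bonf = np.minimum(1.0, p * len(p))
        assert (adj >= p).all()
        assert (adj <= bonf + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=15)
        ref = multipletests(p, method="holm")[1]
        assert holm_adjust(p) == pytest.approx(list(ref))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestCompareCohorts:
    def _table(self, case, control, families=("F1",)):
        data = {}
        labels = {}
        for i, v in enumerate(case):
            data[f"c{i}"] = [v] * len(families)
            labels[f"c{i}"] = "case"
        for i, v in enumerate(control):
            data[f"h{i}"] = [v] * len(families)
            labels[f"h{i}"] = "control"
        return CohortTable(pd.DataFrame(data, index=list(families)), labels)

    def test_constant_table_all_null(self):
        table = self._table([1.0] * 5, [1.0] * 5, families=("F1", "F2"))
        results = compare_cohorts(table)
        assert all(r.p_raw == 1.0 and r.direction == "none" for r in results)

    def test_strong_effect_detected_up_in_case(self):
        rng = np.random.default_rng(8)
        table = self._table(
            list(rng.lognormal(np.log(4.0), 0.3, 20)),
            list(rng.lognormal(0.0, 0.3, 20)),
        )
        (res,) = compare_cohorts(table)
        assert res.direction == "up_in_case"
        assert res.p_adjusted < 0.01
        assert res.fold_change > 2

    def test_single_cohort_rejected(self):
        table = self._table([1.0, 2.0, 3.0], [])
        with pytest.raises(ValueError):
            compare_cohorts(table)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(9)
        fams = tuple(f"F{i}" for i in range(6))
        data = {
            f"c{i}": list(rng.lognormal(0, 0.5, len(fams))) for i in range(8)
        } | {f"h{i}": list(rng.lognormal(0, 0.5, len(fams))) for i in range(8)}
        labels = {f"c{i}": "case" for i in range(8)} | {
            f"h{i}": "control" for i in range(8)
        }
        table = CohortTable(pd.DataFrame(data, index=list(fams)), labels)
        for r in compare_cohorts(table):
            assert r.p_adjusted >= r.p_raw


class TestFamilyRatio:
    def test_simple_ratio(self):
        assert family_ratio({"B": 0.72, "A1": 0.36}, "B", "A1", eps=0) == pytest.approx(2.0)

    def test_zero_denominator_finite(self):
        r = family_ratio({"B": 0.5, "A1": 0.0}, "B", "A1", eps=1e-6)
        assert np.isfinite(r) and r > 1e5

    def test_monotone_in_numerator(self):
        ratios = [family_ratio({"B": b, "A1": 0.4}, "B", "A1") for b in (0.1, 0.5, 2.0)]
        assert ratios == sorted(ratios)

    def test_negative_cpg_rejected(self):
        with pytest.raises(ValueError):
            family_ratio({"B": -0.1, "A1": 0.2}, "B", "A1")
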