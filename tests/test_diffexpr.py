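import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tempodeg as td
from tempodeg.diffexpr import conditional_bh_fdr, log2fc_from_signed


def brute_force_bh(p):
    """Direct step-up definition: q_i = min_{j: p_j ≥ p_i} (m·p_j / rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for k in range(m - 1, -1, -1):
        i = order[k]
        running = min(running, m * p[i] / (k + 1))
        q[i] = min(running, 1.0)
    return q


class TestWelch:
    def test_identical_groups(self):
        t, p = td.welch_t_test([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(1, 2, size=rng.integers(2, 8))
            t, p = td.welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_swap_symmetry(self):
        x, y = [10.0, 11.0, 12.0], [13.0, 14.5, 15.0]
        t1, p1 = td.welch_t_test(x, y)
        t2, p2 = td.welch_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_conventions(self):
        assert td.welch_t_test([5, 5], [5, 5]) == (0.0, 1.0)
        t, p = td.welch_t_test([6, 6], [5, 5])
        assert p == 0.0 and t == np.inf


class TestFoldChange:
    @pytest.mark.parametrize("diff,expected", [(1, 2.0), (-1, -2.0), (0, 1.0), (2.5, 2**2.5)])
    def test_signed_fold_change(self, diff, expected):
        assert td.signed_fold_change(diff, 0.0) == pytest.approx(expected)

    def test_signed_magnitude_at_least_one(self):
        rng = np.random.default_rng(1)
        fc = td.signed_fold_change(rng.normal(size=500), 0.0)
        assert (np.abs(fc) >= 1.0).all()

    def test_log2fc_round_trip(self):
        diffs = np.linspace(-4, 4, 33)
        assert np.allclose(log2fc_from_signed(td.signed_fold_change(diffs, 0.0)), diffs)


class TestBH:
    def test_worked_example(self):
        assert np.allclose(td.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert td.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(td.bh_fdr(p), brute_force_bh(p), rtol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=300)
        q = td.bh_fdr(p)
        assert (q >= p).all() and (q <= 1).all()


class TestConditionalBH:
    def test_worked_example_m_equals_two(self):
        out = conditional_bh_fdr([0.01, 0.2, 0.03, 0.6])
        assert np.allclose(out, [0.02, 1.0, 0.03, 1.0])

    def test_empty_subset_gives_all_ones(self):
        assert (conditional_bh_fdr([0.05, 0.9, 0.31]) == 1.0).all()

    def test_never_larger_than_full_bh_inside_subset(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            p = rng.uniform(size=rng.integers(1, 60))
            full = td.bh_fdr(p)
            cond = conditional_bh_fdr(p)
            mask = p < 0.05
            assert (cond[mask] <= full[mask] + 1e-12).all()


class TestCompareGroups:
    @pytest.fixture()
    def small_design(self):
        rng = np.random.default_rng(8)
        samples = pd.DataFrame(
            {
                "sample_id": [f"t{i}" for i in range(3)] + [f"r{i}" for i in range(3)],
                "group": ["TBI"] * 3 + ["sham"] * 3,
                "treatment": ["vehicle"] * 3 + ["none"] * 3,
                "timepoint": ["d7"] * 3 + ["baseline"] * 3,
                "age_class": ["12wk"] * 6,
            }
        )
        base = rng.uniform(100, 1000, size=50)
        mat = rng.lognormal(np.log(base)[:, None], 0.05, size=(50, 6))
        mat[0, :3] *= 8.0  # planted log2FC = 3 in the first gene
        norm = pd.DataFrame(mat, index=[f"G{i}" for i in range(50)], columns=samples["sample_id"])
        return norm, samples

    def test_planted_effect_flagged_up(self, small_design):
        norm, samples = small_design
        res = td.compare_groups(norm, samples, test={"group": "TBI"}, ref={"group": "sham"})
        row = res[res.gene_id == "G0"].iloc[0]
        assert row.de_flag and row.direction == "up"
        assert row.log2fc == pytest.approx(3.0, abs=0.25)

    def test_invariant_to_column_and_row_order(self, small_design):
        norm, samples = small_design
        res1 = td.compare_groups(norm, samples, test={"group": "TBI"}, ref={"group": "sham"})
        shuffled = norm.iloc[::-1, ::-1]
        samples2 = samples.iloc[::-1].reset_index(drop=True)
        res2 = td.compare_groups(shuffled, samples2, test={"group": "TBI"}, ref={"group": "sham"})
        merged = res1.merge(res2, on="gene_id", suffixes=("_a", "_b"))
        assert np.allclose(merged.p_value_a, merged.p_value_b)
        assert np.allclose(merged.log2fc_a, merged.log2fc_b)

    def test_group_too_small_raises(self, small_design):
        norm, samples = small_design
        with pytest.raises(ValueError, match="≥2 samples"):
            td.compare_groups(norm, samples, test={"sample_id": "t0"}, ref={"group": "sham"})

    def test_de_flag_matches_fdr_threshold(self, small_design):
        norm, samples = small_design
        res = td.compare_groups(norm, samples, test={"group": "TBI"}, ref={"group": "sham"})
        assert (res.de_flag == (res.fdr < 0.05)).all()
        up = res[res.direction == "up"]
        assert (up.log2fc > 0).all() and up.de_flag.all()


class TestComparisonIngestion:
    def test_matches_de_novo_calls(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(100)]
        p = rng.uniform(size=100)
        lfc = rng.normal(size=100)
        comp = pd.DataFrame(
            {
                "gene_id": genes,
                "contrast_id": "d7",
                "fc_signed": td.signed_fold_change(lfc, 0.0),
                "p_value": p,
            }
        )
        res = td.results_from_comparison_table(comp, "d7", fdr_mode="standard")
        assert np.allclose(res.fdr, td.bh_fdr(p))
        assert np.allclose(res.log2fc, lfc)
        assert (res.de_flag == (res.fdr < 0.05)).all()


class TestBaselineRanking:
    def test_descending_with_stable_ties(self):
        norm = pd.DataFrame(
            {"s1": [1000.0, 10.0, 10.0], "s2": [1000.0, 10.0, 10.0]},
            index=["A", "Z", "B"],
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "group": ["sham", "sham"],
                "treatment": ["none", "none"],
                "timepoint": ["baseline", "baseline"],
                "age_class": ["12wk", "12wk"],
            }
        )
        out = td.baseline_expression_ranking(norm, samples)
        assert list(out.gene_id) == ["A", "B", "Z"]
        assert out.mean_count.iloc[0] / out.mean_count.iloc[1] == pytest.approx(100.0)

    def test_empty_subset_gives_empty_table(self):
        norm = pd.DataFrame({"s1": [1.0]}, index=["A"])
        samples = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "group": ["sham"],
                "treatment": ["none"],
                "timepoint": ["baseline"],
                "age_class": ["12wk"],
            }
        )
        assert td.baseline_expression_ranking(norm, samples, gene_subset=[]).empty


@pytest.mark.parametrize("dct,expected", [(0, 1.0), (1, 0.5), (-2, 4.0)])
def test_qpcr_relative_expression(dct, expected):
    assert td.qpcr_relative_expression(dct, 0.0) == pytest.approx(expected)
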