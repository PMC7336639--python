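import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myocomm.de import (
    DEGParams,
    benjamini_hochberg,
    dotplot_stats,
    find_all_markers,
    find_markers,
    log2_fold_change,
    wilcoxon_rank_sum,
)
from conftest import make_normalized


def enumeration_p(x, y):
    """Independent oracle: exact two-sided p by enumerating all C(n, n_x)
    assignments of the pooled tie-free sample."""
    pooled = sorted(x + y)
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n, total = len(pooled), 0
    count = 0
    for combo in itertools.combinations(range(n), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        # two-sided: as or more extreme in either tail
        m = n_x * (n - n_x)
        if min(u, m - u) <= min(u_obs, m - u_obs):
            count += 1
        total += 1
    return count / total


class TestWilcoxon:
    def test_extreme_split_exact(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 5.0] * 10, [1.0, 2.0, 5.0] * 10)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_tied_small_sample(self):
        u, p = wilcoxon_rank_sum([1, 1], [1, 1])
        assert u == 2  # midranks: each comparison contributes 1/2
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n_x,n_y", [(2, 2), (2, 4), (3, 3), (4, 5)])
    def test_matches_enumeration_oracle(self, n_x, n_y, rng):
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n_x + n_y + 1))
            x, y = list(vals[:n_x]), list(vals[n_x:])
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        v = np.log1p([1.0, 2.0])
        assert log2_fold_change(v, v) == 0

    def test_hand_arithmetic(self):
        g = np.log1p([3.0, 3.0])
        r = np.log1p([1.0, 1.0])
        assert log2_fold_change(g, r, pseudocount=1) == pytest.approx(1.0)

    def test_zero_reference(self):
        g = np.log1p([1.0])
        assert log2_fold_change(g, [0.0], pseudocount=1) == pytest.approx(1.0)


class TestBenjaminiHochberg:
    def test_single_p(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_step_up_saturated(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_step_up_two_values(self):
        q = benjamini_hochberg([0.005, 0.1])
        assert np.allclose(q, [0.01, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p_rank_and_permutation_equivariant(self, pvals):
        p = np.array(pvals)
        q = benjamini_hochberg(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(benjamini_hochberg(p[perm]), q[perm])
        assert (q <= 1).all() and (q >= p - 1e-15).all()


def two_group_matrix(rng, n_genes=30, n_per=50, planted=None):
    """Counts-like normalized matrix with exchangeable noise genes and an
    optional planted gene with given delogged group means."""
    lam = rng.gamma(2.0, 1.0, size=n_genes)
    counts = rng.poisson(lam[:, None], size=(n_genes, 2 * n_per)).astype(float)
    if planted is not None:
        mean_a, mean_b = planted
        counts[0, :n_per] = rng.poisson(mean_a, n_per)
        counts[0, n_per:] = rng.poisson(mean_b, n_per)
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return make_normalized(np.log1p(counts)), labels


class TestFindMarkers:
    def test_identical_groups_empty(self):
        # both groups carry the same multiset of values for every gene
        vals = np.log1p(np.array([[3.0, 1.0, 0.0, 3.0, 1.0, 0.0],
                                  [0.0, 2.0, 2.0, 0.0, 2.0, 2.0]]))
        nm = make_normalized(vals)
        labels = np.array(["A"] * 3 + ["B"] * 3)
        assert find_markers(nm, labels, "A", "B").empty

    def test_planted_gene_detected_with_expected_lfc(self, rng):
        nm, labels = two_group_matrix(rng, planted=(4.0, 1.0))
        res = find_markers(nm, labels, "A", "B")
        row = res[res.gene == "G0"]
        assert len(row) == 1
        assert row.q_value.iloc[0] < 0.05
        assert row.avg_log2fc.iloc[0] == pytest.approx(math.log2(5 / 2), abs=0.35)

    def test_antisymmetry_between_group_orders(self, rng):
        nm, labels = two_group_matrix(rng, planted=(4.0, 1.0))
        ab = find_markers(nm, labels, "A", "B").set_index("gene")
        ba = find_markers(nm, labels, "B", "A").set_index("gene")
        assert set(ab.index) == set(ba.index)
        assert np.allclose(ab["avg_log2fc"], -ba.loc[ab.index, "avg_log2fc"])
        assert np.allclose(ab["p_value"], ba.loc[ab.index, "p_value"])

    def test_unknown_label_rejected(self, rng):
        nm, labels = two_group_matrix(rng)
        with pytest.raises(ValueError):
            find_markers(nm, labels, "Z")

    def test_pct_gate_focal_mode(self, rng):
        nm, labels = two_group_matrix(rng, planted=(0.1, 3.0))
        either = find_markers(nm, labels, "A", "B", DEGParams(pct_side="either"))
        focal = find_markers(nm, labels, "A", "B", DEGParams(pct_side="focal"))
        # G0 is barely detected in A: the focal gate must drop it
        assert "G0" in set(either.gene)
        assert "G0" not in set(focal.gene)

    def test_records_sorted_by_lfc_descending(self, rng):
        nm, labels = two_group_matrix(rng, planted=(4.0, 1.0))
        res = find_markers(nm, labels, "A", "B")
        assert (np.diff(res.avg_log2fc) <= 1e-12).all()


class TestFindAllMarkers:
    def test_single_cluster_empty(self, rng):
        nm, _ = two_group_matrix(rng)
        labels = np.array(["only"] * len(nm.cells))
        assert find_all_markers(nm, labels).empty

    def test_disjoint_planted_markers_resolve_to_own_cluster(self, rng):
        n_per = 60
        counts = rng.poisson(1.0, size=(20, 2 * n_per)).astype(float)
        counts[3, :n_per] = rng.poisson(6.0, n_per)   # marker of A
        counts[11, n_per:] = rng.poisson(6.0, n_per)  # marker of B
        nm = make_normalized(np.log1p(counts))
        labels = np.array(["A"] * n_per + ["B"] * n_per)
        res = find_all_markers(nm, labels)
        up = res[(res.q_value < 0.05) & (res.avg_log2fc > 0.5)]
        assert set(up[up.group == "A"].gene) == {"G3"}
        assert set(up[up.group == "B"].gene) == {"G11"}


class TestDotplot:
    def test_hand_arithmetic(self):
        vals = np.array([[0.0, 0.0, 2.0, 2.0]])
        nm = make_normalized(vals)
        out = dotplot_stats(nm, ["k"] * 4, ["G0"])
        assert out.fraction_expressing.iloc[0] == pytest.approx(0.5)
        assert out.mean_expression.iloc[0] == pytest.approx(1.0)

    def test_gene_absent_from_cluster_is_zero(self):
        vals = np.array([[1.0, 1.0, 0.0, 0.0]])
        nm = make_normalized(vals)
        out = dotplot_stats(nm, ["a", "a", "b", "b"], ["G0"]).set_index("cluster")
        assert out.loc["b", "fraction_expressing"] == 0
        assert out.loc["b", "mean_expression"] == 0

    def test_unknown_gene_warned_and_omitted(self):
        nm = make_normalized(np.ones((1, 2)))
        with pytest.warns(UserWarning):
            out = dotplot_stats(nm, ["a", "a"], ["G0", "NOPE"])
        assert set(out.gene) == {"G0"}


def test_null_type_one_error_calibrated(rng):
    """Raw Wilcoxon p under an exchangeable null is near-uniform: the
    p < 0.05 fraction over many NB genes stays close to nominal."""
    counts = rng.negative_binomial(10, 10 / 11, size=(800, 160)).astype(float)
    nm = make_normalized(np.log1p(counts))
    labels = np.array(["A"] * 80 + ["B"] * 80)
    from myocomm.de import _wilcoxon_matrix

    p = _wilcoxon_matrix(
        np.asarray(nm.values[:, :80].todense()), np.asarray(nm.values[:, 80:].todense())
    )
    assert 0.02 <= (p < 0.05).mean() <= 0.08
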