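"""Exact tests, phylogenetic means, patristic distances and PWM scanning."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from condelscan.association_stats import (
    ContingencyTable2x2,
    PositionWeightMatrix,
    boschloo_exact,
    fisher_one_sided,
    mann_whitney_u,
    patristic_distances,
    phylo_mean,
    phylo_welch_t,
    PhyloTree,
    pwm_scan,
    welch_t,
)


# ---------------------------------------------------------------------------
# Boschloo
# ---------------------------------------------------------------------------

def _boschloo_oracle(a, b, c, d, alternative="greater", n_grid=20_001):
    """Independent brute force: enumerate all tables of the conditioned
    margins (outcome columns), score each by scipy's Fisher exact p, and
    sweep the nuisance success probability on a fine grid with local
    polish."""
    n1, n2 = a + c, b + d  # column margins, per the adopted convention
    obs = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1]
    extreme = []
    for x1 in range(n1 + 1):
        for x2 in range(n2 + 1):
            p = sps.fisher_exact(
                [[x1, x2], [n1 - x1, n2 - x2]], alternative=alternative
            )[1]
            if p <= obs * (1 + 1e-12):
                extreme.append((x1, x2))

    def size(pi):
        return sum(
            math.comb(n1, x1) * pi**x1 * (1 - pi) ** (n1 - x1)
            * math.comb(n2, x2) * pi**x2 * (1 - pi) ** (n2 - x2)
            for x1, x2 in extreme
        )

    grid = np.linspace(1e-9, 1 - 1e-9, n_grid)
    vals = [size(p) for p in grid]
    k = int(np.argmax(vals))
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda p: -size(p),
        bounds=(grid[max(0, k - 1)], grid[min(n_grid - 1, k + 1)]),
        method="bounded",
        options={"xatol": 1e-13},
    )
    return obs, min(1.0, max(vals[k], -res.fun))


class TestBoschloo:
    def test_published_enhancer_knockout_association(self):
        """14/175 edited vs 1/236 control fish with the tail phenotype."""
        res = boschloo_exact((14, 161, 1, 235))
        assert res.pvalue == pytest.approx(3.55e-5, rel=0.005)
        assert res.statistic == pytest.approx(4.40e-5, rel=0.005)

    def test_published_gene_knockout_association(self):
        """16/265 edited vs 0/277 control fish with the tail phenotype."""
        res = boschloo_exact((16, 249, 0, 277))
        assert res.pvalue == pytest.approx(6.66e-6, rel=0.005)
        assert res.statistic == pytest.approx(8.40e-6, rel=0.005)

    def test_no_outcome_variation(self):
        res = boschloo_exact((0, 5, 0, 5))
        assert (res.statistic, res.pvalue) == (1.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ContingencyTable2x2(0, 0, 3, 2)

    @pytest.mark.parametrize(
        "table",
        [(3, 1, 0, 4), (5, 2, 1, 6), (2, 6, 5, 1), (4, 4, 2, 2), (1, 7, 6, 2)],
    )
    def test_one_sided_matches_bruteforce_oracle(self, table):
        a, b, c, d = table
        for alternative in ("greater", "less"):
            mine = boschloo_exact(table, alternative=alternative)
            obs, p = _boschloo_oracle(a, b, c, d, alternative)
            assert mine.statistic == pytest.approx(obs, abs=1e-12)
            assert mine.pvalue == pytest.approx(p, abs=1e-9)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(12):
            n1, n2 = rng.integers(2, 20, size=2)
            a, c = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            tab = [[int(a), int(n1 - a)], [int(c), int(n2 - c)]]
            if a + c == 0 or (n1 - a) + (n2 - c) == 0:
                continue
            mine = boschloo_exact(tab)
            ref = sps.boschloo_exact(tab, alternative="two-sided", n=128)
            assert mine.statistic == pytest.approx(float(ref.statistic), rel=1e-9)
            assert mine.pvalue == pytest.approx(float(ref.pvalue), rel=1e-4)

    def test_dominates_fisher_small_sweep(self):
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        tab = (a, n1 - a, c, n2 - c)
                        if a + c == 0 or (n1 - a) + (n2 - c) == 0:
                            continue
                        res = boschloo_exact(tab, alternative="greater",
                                             grid_points=2001)
                        fisher = fisher_one_sided(tab, "greater")
                        assert 0 < res.pvalue <= fisher + 1e-12
                        assert res.statistic == pytest.approx(fisher)

    def test_row_swap_flips_alternative(self):
        tab = (7, 3, 2, 8)
        swapped = (2, 8, 7, 3)
        g = boschloo_exact(tab, alternative="greater")
        l = boschloo_exact(swapped, alternative="less")
        assert g.pvalue == pytest.approx(l.pvalue, rel=1e-9)
        assert g.statistic == pytest.approx(l.statistic, rel=1e-12)


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == 1

    def test_closed_form_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=9), rng.normal(1, 2, size=14)
        t, df, p = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_calibration(self):
        """Type-I error at alpha=0.05 under the null, n=20 per group."""
        rng = np.random.default_rng(7)
        reps = 10_000
        x = rng.normal(size=(reps, 20))
        y = rng.normal(size=(reps, 20))
        rejections = sum(welch_t(xi, yi)[2] < 0.05 for xi, yi in zip(x, y))
        assert 0.045 <= rejections / reps <= 0.055

    def test_phylo_welch_reduces_to_welch_on_star_tree(self):
        tree = PhyloTree("(a:1,b:1,c:1,d:1,e:1,f:1);")
        vals = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 7.0, "e": 8.0, "f": 9.0}
        got = phylo_welch_t(tree, vals, ["a", "b", "c"], ["d", "e", "f"])
        ref = welch_t([1, 2, 3], [7, 8, 9])
        assert got == pytest.approx(ref)


# ---------------------------------------------------------------------------
# Phylogenetic means and distances
# ---------------------------------------------------------------------------

class TestPhyloMean:
    def test_star_tree_is_arithmetic_mean(self):
        assert phylo_mean("(a:1,b:1,c:1);", {"a": 1, "b": 2, "c": 3}) == pytest.approx(2.0)

    def test_three_tip_hand_inverted(self):
        # V = [[2,1,0],[1,2,0],[0,0,2]]; solved by hand -> 3.0
        assert phylo_mean("((A:1,B:1):1,C:2);", {"A": 0, "B": 0, "C": 7}) == pytest.approx(3.0)

    def test_pruning_invariance(self):
        full = phylo_mean("((A:1,B:1):1,(C:2,D:1):0.5);", {"A": 0, "B": 0, "C": 7})
        pruned = phylo_mean("((A:1,B:1):1,C:2.5);", {"A": 0, "B": 0, "C": 7})
        assert full == pytest.approx(pruned)

    def test_bounded_by_value_range(self):
        rng = np.random.default_rng(5)
        vals = {k: float(v) for k, v in zip("ABCD", rng.normal(size=4))}
        m = phylo_mean("((A:0.5,B:1.2):0.3,(C:0.8,D:0.2):1.1);", vals)
        assert min(vals.values()) <= m <= max(vals.values())

    def test_duplicate_zero_length_tips_singular(self):
        with pytest.raises(ValueError, match="singular"):
            phylo_mean("((A:0,B:0):1,C:2);", {"A": 1, "B": 2, "C": 3})

    def test_unknown_tip_rejected(self):
        with pytest.raises(ValueError, match="unknown tips"):
            phylo_mean("(a:1,b:1);", {"z": 1.0, "a": 2.0})


def _paths_to_root(tree_str):
    """Oracle helper: per-tip dict of (edge id -> length) along root path."""
    import dendropy

    tree = dendropy.Tree.get(data=tree_str, schema="newick")
    paths = {}
    for leaf in tree.leaf_node_iter():
        node, path = leaf, {}
        while node.parent_node is not None:
            path[id(node)] = node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = path
    return paths


class TestPatristic:
    def test_three_tip_example(self):
        labels, d = patristic_distances("((A:1,B:1):1,C:2);")
        i = {lbl: k for k, lbl in enumerate(labels)}
        assert d[i["A"], i["B"]] == pytest.approx(2)
        assert d[i["A"], i["C"]] == pytest.approx(4)
        assert d[i["B"], i["C"]] == pytest.approx(4)

    def test_star_tree(self):
        labels, d = patristic_distances("(a:3,b:3,c:3);")
        off = d[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 6.0)
        assert np.allclose(np.diag(d), 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_trees_match_path_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def grow(labels):
            if len(labels) == 1:
                return f"{labels[0]}:{rng.uniform(0.1, 2):.3f}"
            k = rng.integers(1, len(labels))
            return (
                f"({grow(labels[:k])},{grow(labels[k:])}):{rng.uniform(0.1, 2):.3f}"
            )

        labels = [f"t{i}" for i in range(6)]
        newick = f"({grow(labels[:3])},{grow(labels[3:])});"
        tips, d = patristic_distances(newick)
        paths = _paths_to_root(newick)
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                pa, pb = paths[a], paths[b]
                shared = set(pa) & set(pb)
                expect = sum(v for k, v in pa.items() if k not in shared)
                expect += sum(v for k, v in pb.items() if k not in shared)
                assert d[i, j] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_enumeration(x, y):
    """All C(m+n, m) rank assignments of the observed pooled values."""
    pooled = sorted(x + y)
    m, n = len(x), len(y)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    for combo in itertools.combinations(range(m + n), m):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(m + n) if i not in combo]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_extreme_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_single_equal_values(self):
        u, p = mann_whitney_u([5.0], [5.0])
        assert p == 1.0

    @pytest.mark.parametrize("m,n", [(2, 3), (3, 3), (4, 4), (5, 5), (3, 7)])
    def test_exact_branch_matches_enumeration(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        x = list(rng.permutation(np.arange(1.0, m + n + 1))[:m])
        y = [v for v in np.arange(1.0, m + n + 1) if v not in x]
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = _mwu_enumeration(x, y)
        assert u == u_ref
        assert p == pytest.approx(p_ref)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(11)
        x = list(rng.normal(size=8))
        y = list(rng.normal(0.5, size=9))
        u, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_approximation_close_to_exact_at_ten_per_group(self):
        rng = np.random.default_rng(2)
        x = list(rng.normal(size=10))
        y = list(rng.normal(0.3, size=10))
        _, p_exact = mann_whitney_u(x, y)
        # force the approximation by appending a tie far from the data
        _, p_big = mann_whitney_u(x + [99.0], y + [99.0])
        ref = sps.mannwhitneyu(
            x + [99.0], y + [99.0], alternative="two-sided", method="asymptotic"
        )
        assert p_big == pytest.approx(ref.pvalue, abs=1e-9)
        assert abs(p_big - p_exact) < 0.1  # sanity, not equality


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

@pytest.fixture()
def pwm():
    # non-palindromic consensus ACGA so strand assignment is unambiguous
    counts = np.array(
        [
            [8, 0, 1, 8],
            [0, 8, 1, 0],
            [0, 0, 6, 0],
            [0, 0, 0, 0],
        ],
        dtype=float,
    )
    return PositionWeightMatrix("M1", counts)


class TestPwm:
    def test_consensus_scores_1000(self, pwm):
        assert pwm.consensus == "ACGA"
        assert pwm.rel_score("ACGA") == pytest.approx(1000.0)

    def test_anticonsensus_scores_0(self, pwm):
        anti = "".join(
            "ACGT"[i] for i in pwm.log_odds.argmin(axis=0)
        )
        assert pwm.rel_score(anti) == pytest.approx(0.0)

    def test_threshold_and_positions(self, pwm):
        seq = "TTTTACGATTTT"
        hits = pwm_scan(seq, pwm, min_rel_score=925)
        assert [(h.position, h.strand) for h in hits] == [(4, "+")]

    def test_reverse_complement_symmetry(self, pwm):
        seq = "GGGACGACCCCCTCGTGG"
        fwd = pwm_scan(seq, pwm, min_rel_score=900)
        from condelscan.conserved_elements import revcomp

        rev = pwm_scan(revcomp(seq), pwm, min_rel_score=900)
        L = len(pwm)
        mirrored = sorted(
            (len(seq) - L - h.position, "+-"[h.strand == "+"], round(h.rel_score, 6))
            for h in rev
        )
        assert mirrored == sorted(
            (h.position, h.strand, round(h.rel_score, 6)) for h in fwd
        )

    def test_n_windows_skipped(self, pwm):
        assert pwm_scan("ACNT", pwm, min_rel_score=0) == []

    def test_matrix_longer_than_sequence(self, pwm):
        assert pwm_scan("AC", pwm) == []
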