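"""Association statistics used around the deletion screen.

Implements Boschloo's unconditional exact test for 2x2 tables (the
genotype-phenotype association test for genome-editing outcomes), Welch's
t, the Mann-Whitney U test, phylogenetic generalized-least-squares means
under Brownian motion, patristic distance matrices, and position-weight-
matrix scanning with JASPAR-style relative scores.

Boschloo's test conditions on only one margin (the per-group sample
sizes): the test statistic is the one-sided Fisher exact p-value of the
observed table, and the p-value is the supremum over the common success
probability pi of the chance, under two independent binomials, of a table
at least as extreme.  The supremum is taken on a dense pi grid with local
bounded refinement.  The two-sided p doubles the smaller one-sided
p-value (capped at 1) and reports that side's Fisher statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# Boschloo's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) for group 1 and (c, d) for group 2; rows are groups,
    columns are outcome (success, failure).  Row sums n1 = a + b and
    n2 = c + d are the fixed design margins."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table entries must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both group sizes must be positive")


@dataclass(frozen=True)
class ExactTestResult:
    statistic: float
    pvalue: float


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape == (2, 2):
        return ContingencyTable2x2(*(int(x) for x in arr.ravel()))
    if arr.shape == (4,):
        return ContingencyTable2x2(*(int(x) for x in arr))
    raise ValueError("table must be 2x2 or a flat (a, b, c, d)")


def _fisher_stat_grid(n1: int, n2: int, alternative: str) -> np.ndarray:
    """One-sided Fisher exact p for every table (x1, x2), vectorized.

    'greater' tests whether group 1's success proportion exceeds group 2's.
    """
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    total = x1 + x2
    if alternative == "greater":
        return stats.hypergeom.sf(x1 - 1, n1 + n2, total, n1)
    if alternative == "less":
        return stats.hypergeom.cdf(x1, n1 + n2, total, n1)
    raise ValueError(f"bad alternative {alternative!r}")


def _size_at(pi: np.ndarray, mask, n1: int, n2: int) -> np.ndarray:
    """P(table in rejection set) at each nuisance pi, under independence."""
    pi = np.atleast_1d(np.asarray(pi, dtype=float))
    p1 = stats.binom.pmf(np.arange(n1 + 1)[None, :], n1, pi[:, None])
    p2 = stats.binom.pmf(np.arange(n2 + 1)[None, :], n2, pi[:, None])
    return np.einsum("ki,ij,kj->k", p1, mask, p2)


def _boschloo_one_sided(
    t: ContingencyTable2x2,
    alternative: str,
    grid_points: int,
    refine: bool,
    condition_on: str = "columns",
) -> ExactTestResult:
    if condition_on == "columns":
        # The convention of the reference implementation this field uses:
        # the two binomial samples are the outcome columns (sizes a+c and
        # b+d).  The observed-table Fisher statistic is transpose-invariant,
        # so only the nuisance maximization is affected.
        t = ContingencyTable2x2(t.a, t.c, t.b, t.d)
    elif condition_on != "rows":
        raise ValueError(f"bad condition_on {condition_on!r}")
    n1, n2 = t.a + t.b, t.c + t.d
    fisher = _fisher_stat_grid(n1, n2, alternative)
    stat = float(fisher[t.a, t.c])
    # tables at least as extreme: Fisher p no larger than observed (tiny
    # relative tolerance guards against float noise among equal tables)
    mask = (fisher <= stat * (1 + 1e-12)).astype(float)
    grid = np.linspace(1e-9, 1 - 1e-9, grid_points)
    sizes = _size_at(grid, mask, n1, n2)
    k = int(np.argmax(sizes))
    pval = float(sizes[k])
    if refine:
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]
        res = optimize.minimize_scalar(
            lambda p: -_size_at(p, mask, n1, n2)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        pval = max(pval, float(-res.fun))
    return ExactTestResult(stat, min(pval, 1.0))


def boschloo_exact(
    table,
    alternative: str = "two-sided",
    grid_points: int = 10001,
    refine: bool = True,
    condition_on: str = "columns",
) -> ExactTestResult:
    """Boschloo's unconditional exact test for a 2x2 table.

    Parameters
    ----------
    table : 2x2 array, flat (a, b, c, d), or :class:`ContingencyTable2x2`
        Rows are groups with fixed sizes, columns are outcome counts.
    alternative : {"two-sided", "less", "greater"}
        Direction of group 1's success proportion relative to group 2's.
    grid_points : int
        Density of the nuisance-parameter grid on (0, 1).
    refine : bool
        Locally refine the supremum around the best grid point.
    condition_on : {"columns", "rows"}
        Which margin the pair of nuisance binomials fixes.  The default
        mirrors the reference implementation used throughout this field
        (the two samples are the outcome columns); "rows" conditions on
        the group sizes instead.  The test statistic is identical either
        way.

    Returns
    -------
    ExactTestResult
        ``statistic`` is the one-sided Fisher exact p-value of the observed
        table in the tested direction (the smaller side for two-sided);
        ``pvalue`` is the unconditional exact p.  Two-sided doubles the
        smaller one-sided p (capped at 1).
    """
    t = _as_table(table)
    if t.a + t.c == 0 or t.b + t.d == 0:
        # no variation in outcome: every table equally extreme
        return ExactTestResult(1.0, 1.0)
    if alternative in ("less", "greater"):
        return _boschloo_one_sided(t, alternative, grid_points, refine, condition_on)
    if alternative != "two-sided":
        raise ValueError(f"bad alternative {alternative!r}")
    less = _boschloo_one_sided(t, "less", grid_points, refine, condition_on)
    greater = _boschloo_one_sided(t, "greater", grid_points, refine, condition_on)
    side = less if less.pvalue < greater.pvalue else greater
    return ExactTestResult(side.statistic, min(1.0, 2 * side.pvalue))


def fisher_one_sided(table, alternative: str = "greater") -> float:
    """One-sided Fisher exact p (the Boschloo test statistic)."""
    t = _as_table(table)
    grid = _fisher_stat_grid(t.a + t.b, t.c + t.d, alternative)
    return float(grid[t.a, t.c])


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    sx, sy = vx / len(x), vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# Phylogenetic tree machinery
# ---------------------------------------------------------------------------

class PhyloTree:
    """A rooted tree with branch lengths, for GLS means and distances.

    The Brownian-motion covariance between two tips is the shared
    root-to-tip path length; V is built from tip depths and patristic
    distances.
    """

    def __init__(self, tree) -> None:
        import dendropy

        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick")
        self._tree = tree
        self.tip_labels: list[str] = []
        depths: list[float] = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else str(leaf)
            if label in self.tip_labels:
                raise ValueError(f"duplicate tip label {label!r}")
            self.tip_labels.append(label)
            depths.append(self._depth(leaf))
        self._depths = np.array(depths)

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        from .formats_io import read_newick

        return cls(read_newick(source))

    @staticmethod
    def _depth(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    def patristic_matrix(self) -> np.ndarray:
        """Tip-to-tip path lengths, ordered as ``tip_labels``."""
        import dendropy

        pdm = self._tree.phylogenetic_distance_matrix()
        n = len(self.tip_labels)
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        d = np.zeros((n, n))
        for i, a in enumerate(self.tip_labels):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(
                    taxa[a], taxa[self.tip_labels[j]]
                )
        return d

    def shared_path_matrix(self) -> np.ndarray:
        """Brownian covariance V: shared root-to-tip branch length."""
        d = self.patristic_matrix()
        dep = self._depths
        v = (dep[:, None] + dep[None, :] - d) / 2.0
        np.fill_diagonal(v, dep)
        return v


def patristic_distances(tree) -> tuple[list[str], np.ndarray]:
    """Labels and symmetric patristic distance matrix of a tree."""
    pt = tree if isinstance(tree, PhyloTree) else PhyloTree(tree)
    return pt.tip_labels, pt.patristic_matrix()


def phylo_mean(tree, tip_values: Mapping[str, float]) -> float:
    """GLS (Brownian-motion) estimate of a trait's root mean.

    Tips absent from ``tip_values`` are pruned, which leaves the estimate
    unchanged for the remaining tips.  mean = (1' V^-1 1)^-1 1' V^-1 y.
    """
    pt = tree if isinstance(tree, PhyloTree) else PhyloTree(tree)
    missing = set(tip_values) - set(pt.tip_labels)
    if missing:
        raise ValueError(f"values given for unknown tips: {sorted(missing)}")
    keep = [i for i, lbl in enumerate(pt.tip_labels) if lbl in tip_values]
    if not keep:
        raise ValueError("no valued tips")
    v = pt.shared_path_matrix()[np.ix_(keep, keep)]
    y = np.array([tip_values[pt.tip_labels[i]] for i in keep])
    one = np.ones(len(keep))
    try:
        viy = np.linalg.solve(v, y)
        vi1 = np.linalg.solve(v, one)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance matrix: {exc}") from exc
    return float(one @ viy / (one @ vi1))


def phylo_welch_t(
    tree,
    tip_values: Mapping[str, float],
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[float, float, float]:
    """Welch's t comparing phylogenetically corrected group means.

    Group means are GLS estimates on the subtree of each group's tips;
    dispersion comes from the raw per-species values (the group means are
    shifted to the corrected estimates before the classical Welch
    computation).  This is a documented interpretation of combining
    tree-corrected means with a Welch comparison.
    """
    xa = np.array([tip_values[s] for s in group_a], dtype=float)
    xb = np.array([tip_values[s] for s in group_b], dtype=float)
    ma = phylo_mean(tree, {s: tip_values[s] for s in group_a})
    mb = phylo_mean(tree, {s: tip_values[s] for s in group_b})
    return welch_t(xa - xa.mean() + ma, xb - xb.mean() + mb)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_counts(m: int, n: int) -> np.ndarray:
    """Number of rank assignments giving each U value (0..m*n).

    Gaussian-binomial recurrence N(i,j,u) = N(i,j-1,u) + N(i-1,j,u-j).
    """
    size = m * n + 1
    table = np.zeros((m + 1, n + 1, size))
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            table[i, j] = table[i, j - 1]
            table[i, j, j:] += table[i - 1, j, : size - j]
    return table[m, n]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test.

    Exact enumeration of the U distribution when m + n <= 20 and the data
    have no ties; otherwise the normal approximation with tie correction
    and continuity correction.  Returns ``(U, p)`` with U the statistic of
    sample ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    rx = ranks[:m].sum()
    u = rx - m * (m + 1) / 2.0
    has_ties = len(np.unique(combined)) < m + n
    if m + n <= 20 and not has_ties:
        dist = _u_counts(m, n)
        total = dist.sum()
        ui = int(round(u))
        p_le = dist[: ui + 1].sum() / total
        p_ge = dist[ui:].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            raise ValueError(f"bad alternative {alternative!r}")
        return float(u), float(p)
    # normal approximation with tie correction
    mu = m * n / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((m + n) * (m + n - 1))
    sigma2 = m * n / 12.0 * ((m + n + 1) - tie_term)
    if sigma2 == 0:
        return float(u), 1.0
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u - mu) - 0.5) / sigma
        p = 2 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sigma
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"bad alternative {alternative!r}")
    return float(u), float(min(1.0, p))


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class PwmHit:
    position: int
    strand: str
    rel_score: float


class PositionWeightMatrix:
    """A JASPAR-style PFM with derived log-odds and relative scoring.

    ``counts`` is a 4 x L matrix in A/C/G/T row order.  Log-odds uses a
    uniform 0.25 background and a total pseudocount (default 0.8) split by
    background, the common TFBS-scanning convention.  The relative score
    of a window rescales its log-odds to [0, 1000] between the matrix's
    attainable minimum and maximum.
    """

    def __init__(
        self,
        matrix_id: str,
        counts: np.ndarray,
        name: str | None = None,
        pseudocount: float = 0.8,
        background: float = 0.25,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.matrix_id = matrix_id
        self.name = name or matrix_id
        self.counts = counts
        adj = counts + pseudocount * background
        freqs = adj / adj.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(freqs / background)
        self._min = self.log_odds.min(axis=0).sum()
        self._max = self.log_odds.max(axis=0).sum()

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.log_odds.argmax(axis=0))

    def rel_score(self, window: str) -> float:
        """Relative match score of one window, scaled to [0, 1000]."""
        if len(window) != len(self):
            raise ValueError("window length must equal matrix length")
        idx = [_BASE_INDEX[b] for b in window.upper()]
        raw = float(self.log_odds[idx, np.arange(len(self))].sum())
        return 1000.0 * (raw - self._min) / (self._max - self._min)


def pwm_scan(
    sequence: str,
    pwm: PositionWeightMatrix,
    min_rel_score: float = 925.0,
) -> list[PwmHit]:
    """Scan both strands for PWM matches with relative score >= threshold.

    Positions are 0-based window starts on the forward sequence for both
    strands; windows containing N are skipped.  Returns hits sorted by
    position.
    """
    L = len(pwm)
    if L > len(sequence):
        return []
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    idx = lut[codes]
    n_wins = len(seq) - L + 1
    offsets = np.arange(L)
    win_idx = idx[np.arange(n_wins)[:, None] + offsets]
    valid = (win_idx >= 0).all(axis=1)
    lo = pwm.log_odds
    rc_lo = lo[::-1, ::-1]  # reverse-complement matrix scores the '-' strand
    hits: list[PwmHit] = []
    for strand, mat in (("+", lo), ("-", rc_lo)):
        raw = np.where(
            valid,
            mat[np.clip(win_idx, 0, 3), offsets[None, :]].sum(axis=1),
            -np.inf,
        )
        rel = 1000.0 * (raw - pwm._min) / (pwm._max - pwm._min)
        for pos in np.flatnonzero(valid & (rel >= min_rel_score)):
            hits.append(PwmHit(int(pos), strand, float(rel[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
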