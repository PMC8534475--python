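"""Alpha/beta diversity and the two hypothesis tests, from first principles.

Implements OTU richness, Shannon diversity (base-2 default), root-inclusive
Faith's phylogenetic diversity, weighted UniFrac (unnormalized by default),
classical PCoA by double-centering, an exact/approximate Mann-Whitney U
test, and PERMANOVA with label permutations.  These are written directly
from their definitions; library implementations serve only as independent
cross-checks in the test suite.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
import skbio


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def richness(column: pd.Series | np.ndarray) -> int:
    """Number of features with count > 0."""
    return int((np.asarray(column) > 0).sum())


def shannon(column: pd.Series | np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log p_i on proportions; zero-count
    features contribute nothing."""
    x = np.asarray(column, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("empty sample: cannot compute Shannon diversity")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(column: pd.Series, tree: skbio.TreeNode) -> float:
    """Faith's PD: total branch length of the minimal subtree connecting the
    observed tips to the root (root-inclusive convention)."""
    observed = [str(i) for i, v in column.items() if v > 0]
    tips = {t.name: t for t in tree.tips()}
    missing = [o for o in observed if o not in tips]
    if missing:
        raise ValueError(f"observed tips absent from tree: {missing}")
    seen = set()
    total = 0.0
    for name in observed:
        node = tips[name]
        while node.parent is not None:
            if id(node) in seen:
                break
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


# ---------------------------------------------------------------------------
# Weighted UniFrac
# ---------------------------------------------------------------------------

def _tree_arrays(tree: skbio.TreeNode, tip_order: list[str]):
    """Decompose a tree into (branch lengths, branch-by-tip incidence)."""
    tip_index = {name: j for j, name in enumerate(tip_order)}
    lengths = []
    incidence = []
    for node in tree.postorder(include_self=False):
        row = np.zeros(len(tip_order), dtype=bool)
        for tip in node.tips(include_self=True):
            j = tip_index.get(tip.name)
            if j is None:
                raise ValueError(f"tree tip {tip.name!r} not among table features")
            row[j] = True
        lengths.append(node.length or 0.0)
        incidence.append(row)
    return np.array(lengths), np.array(incidence)


def _tip_depths(tree: skbio.TreeNode, tip_order: list[str]) -> np.ndarray:
    depths = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths[tip.name] = d
    return np.array([depths[name] for name in tip_order])


def weighted_unifrac(
    a: pd.Series,
    b: pd.Series,
    tree: skbio.TreeNode,
    normalized: bool = False,
) -> float:
    """Weighted UniFrac distance between two samples.

    Unnormalized: sum over branches of l_b * |p_a(b) - p_b(b)| where p_x(b)
    is the fraction of sample x's reads on tips below the branch.  The
    normalized variant divides by the abundance-weighted maximum (the
    root-to-tip-depth-weighted sum of both samples' tip proportions).
    """
    if not a.index.equals(b.index):
        b = b.reindex(a.index)
        if b.isna().any():
            raise ValueError("samples index mismatch")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both samples must be non-empty")
    tip_order = list(a.index.astype(str))
    lengths, incidence = _tree_arrays(tree, tip_order)
    pa = a.to_numpy(dtype=float) / a.sum()
    pb = b.to_numpy(dtype=float) / b.sum()
    d = float((lengths * np.abs(incidence @ pa - incidence @ pb)).sum())
    if not normalized:
        return d
    depths = _tip_depths(tree, tip_order)
    denom = float((depths * (pa + pb)).sum())
    return d / denom if denom > 0 else 0.0


def beta_diversity(
    table: pd.DataFrame,
    tree: skbio.TreeNode,
    normalized: bool = False,
) -> pd.DataFrame:
    """All-pairs weighted UniFrac distance matrix for a feature-by-sample table."""
    tip_order = list(table.index.astype(str))
    lengths, incidence = _tree_arrays(tree, tip_order)
    x = table.to_numpy(dtype=float)
    sums = x.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("all samples must be non-empty")
    p = x / sums
    branch_mass = incidence.astype(float).T  # tips x branches
    masses = p.T @ branch_mass               # samples x branches
    n = table.shape[1]
    out = np.zeros((n, n))
    depths = _tip_depths(tree, tip_order) if normalized else None
    for i in range(n):
        for j in range(i + 1, n):
            d = float((lengths * np.abs(masses[i] - masses[j])).sum())
            if normalized:
                denom = float((depths * (p[:, i] + p[:, j])).sum())
                d = d / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=table.columns, columns=table.columns)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dist: pd.DataFrame):
    """Classical PCoA: double-center -0.5 * D^2, eigendecompose, order axes
    by descending eigenvalue.

    Returns ``(coordinates, proportion_explained, eigenvalues)``.  Negative
    eigenvalues are reported but excluded from the proportion-explained
    denominator; their axes carry zero coordinates.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(pos)
    pos_sum = pos.sum()
    proportion = pos / pos_sum if pos_sum > 0 else np.zeros(n)
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(n))
    axes = [f"PC{i + 1}" for i in range(n)]
    return (
        pd.DataFrame(coords, index=ids, columns=axes),
        pd.Series(proportion, index=axes, name="proportion_explained"),
        pd.Series(eigvals, index=axes, name="eigenvalue"),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value for group sizes n, m."""
    # f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u)
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)
    b = _u_counts(n, m - 1)
    size = n * m + 1
    out = [0] * size
    for u in range(size):
        if 0 <= u - m < len(a):
            out[u] += a[u - m]
        if u < len(b):
            out[u] += b[u]
    return tuple(out)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test.  Exact p by enumeration when n_x + n_y <= 20 and
    there are no ties; otherwise normal approximation with tie and
    continuity corrections.  Returns ``(U, p)`` with U the statistic of x
    (number of (x > y) pairs, ties counting one half)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = len(x), len(y)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    u = float(gt) + 0.5 * float(eq)

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if nx + ny <= 20 and not has_ties:
        counts = _u_counts(nx, ny)
        total = sum(counts)
        ui = int(round(u))
        p_le = sum(counts[: ui + 1]) / total
        p_ge = sum(counts[ui:]) / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
        return u, float(p)

    from scipy.stats import norm, rankdata

    mu = nx * ny / 2.0
    n = nx + ny
    ranks = rankdata(pooled)
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = max(0.0, abs(u - mu) - 0.5) / sd
        p = 2.0 * float(norm.sf(z))
    elif alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = float(norm.sf(z))
    else:
        z = (u - mu + 0.5) / sd
        p = float(norm.cdf(z))
    return u, min(1.0, p)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dist: pd.DataFrame,
    groups: pd.Series | dict,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational MANOVA on a distance matrix.

    pseudo-F = ((SS_total - SS_within) / (k - 1)) / (SS_within / (N - k));
    p = (#{permuted F >= observed F} + 1) / (n_perm + 1).  Samples are
    canonically ordered by id before drawing permutations, so the result is
    invariant to input sample order for a fixed seed.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    ids = sorted(dist.index)
    d = dist.loc[ids, ids].to_numpy(dtype=float)
    labels = groups.loc[ids].to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA requires >= 2 groups")
    if (counts < 2).any():
        small = [str(g) for g, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    n, k = len(ids), len(uniq)
    d2 = d ** 2

    ss_total, ss_within = _permanova_ss(d2, labels, uniq)
    f_obs = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))

    rng = np.random.default_rng(seed)
    # vectorized permutations: gather within-group squared distances
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ss_within_perm = np.zeros(n_perm)
    for g in uniq:
        pos = np.flatnonzero(labels == g)
        sub_idx = perms[:, pos]                          # n_perm x n_g
        block = d2[sub_idx[:, :, None], sub_idx[:, None, :]]
        ss_within_perm += block.sum(axis=(1, 2)) / (2.0 * len(pos))
    f_perm = ((ss_total - ss_within_perm) / (k - 1)) / (ss_within_perm / (n - k))
    # a float tolerance so permutations reproducing the observed partition
    # count as ties despite summation-order rounding
    tol = 1e-9 * (1.0 + abs(f_obs))
    p = (np.count_nonzero(f_perm >= f_obs - tol) + 1) / (n_perm + 1)
    return float(f_obs), float(p)
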