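"""Independent brute-force oracles for the diversity statistics.

Each oracle computes the quantity from its definition by a different route
than the package implementation (explicit per-branch traversal, exhaustive
enumeration of subsets/rank splits), so agreement is meaningful.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def branch_sets(tree):
    """(length, set-of-descendant-tip-names) for every non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips(include_self=True)}
        out.append((node.length or 0.0, tips))
    return out


def faith_pd_bruteforce(observed: set[str], tree) -> float:
    """Sum of lengths of branches with at least one observed tip below."""
    return sum(l for l, tips in branch_sets(tree) if tips & observed)


def weighted_unifrac_bruteforce(a: dict, b: dict, tree, normalized=False) -> float:
    ta, tb = sum(a.values()), sum(b.values())
    d = 0.0
    for l, tips in branch_sets(tree):
        pa = sum(a.get(t, 0) for t in tips) / ta
        pb = sum(b.get(t, 0) for t in tips) / tb
        d += l * abs(pa - pb)
    if not normalized:
        return d
    # abundance-weighted maximum: root-to-tip depths weighted by proportions
    denom = 0.0
    for tip in tree.tips():
        depth, node = 0.0, tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        denom += depth * (a.get(tip.name, 0) / ta + b.get(tip.name, 0) / tb)
    return d / denom if denom else 0.0


def shannon_bruteforce(counts, base=2.0) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log(p) / np.log(base)
    return h


def rarefaction_bruteforce(counts, depth: int) -> float:
    """Exact E[richness] by enumerating every subset of ``depth`` reads."""
    pool = [i for i, c in enumerate(counts) for _ in range(int(c))]
    vals = [len(set(sub)) for sub in itertools.combinations(pool, depth)]
    return float(np.mean(vals))


def mann_whitney_exact_bruteforce(x, y, alternative="two-sided"):
    """Exact U and p by enumerating all rank splits (no ties assumed)."""
    nx, ny = len(x), len(y)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    pooled = sorted(list(x) + list(y))
    n = nx + ny
    us = []
    for x_pos in itertools.combinations(range(n), nx):
        xs = [pooled[i] for i in x_pos]
        ys = [pooled[i] for i in range(n) if i not in x_pos]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":
        p = p_ge
    else:
        p = p_le
    return float(u_obs), float(p)


def permanova_f_bruteforce(d, labels):
    """Pseudo-F from the definition, with explicit double loops."""
    n = len(labels)
    groups = sorted(set(labels))
    k = len(groups)
    ss_t = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(d[i][j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    return ((ss_t - ss_w) / (k - 1)) / (ss_w / (n - k))


def random_tree(n_tips: int, rng: np.random.Generator):
    """Random bifurcating tree with uniform branch lengths as a TreeNode."""
    import skbio

    names = [f"t{i}" for i in range(n_tips)]
    nodes = [f"{n}:{rng.uniform(0.1, 2.0):.6f}" for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.6f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] if ")" in nodes[0] else nodes[0]
    tree = skbio.TreeNode.read([newick + ";"], convert_underscores=False)
    return tree, names
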