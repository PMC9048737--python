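"""Brute-force reference implementations used only to cross-check the
library. They enumerate every tree edge / label permutation directly and are
kept deliberately independent of the code paths they verify."""

from itertools import combinations

import numpy as np


def _edges_with_tipsets(tree):
    """(branch length, descendant tip-name set) for every non-root edge."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        out.append((node.length, frozenset(tips)))
    return out


def unifrac_unweighted_bruteforce(a_counts, b_counts, taxa, tree) -> float:
    a = {t for t, c in zip(taxa, a_counts) if c > 0}
    b = {t for t, c in zip(taxa, b_counts) if c > 0}
    unique = shared_union = 0.0
    for length, tips in _edges_with_tipsets(tree):
        in_a, in_b = bool(tips & a), bool(tips & b)
        if in_a or in_b:
            shared_union += length
            if in_a != in_b:
                unique += length
    return unique / shared_union if shared_union else 0.0


def unifrac_weighted_bruteforce(a_counts, b_counts, taxa, tree, normalized) -> float:
    a = np.asarray(a_counts, dtype=float)
    b = np.asarray(b_counts, dtype=float)
    pa = dict(zip(taxa, a / a.sum()))
    pb = dict(zip(taxa, b / b.sum()))
    num = den = 0.0
    for length, tips in _edges_with_tipsets(tree):
        ma = sum(pa.get(t, 0.0) for t in tips)
        mb = sum(pb.get(t, 0.0) for t in tips)
        num += length * abs(ma - mb)
        den += length * (ma + mb)
    if not normalized:
        return num
    return num / den if den else 0.0


def permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances (direct partition)."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    return (ssa / (a - 1)) / (ssw / (n - a))


def permanova_exhaustive_p(dm, labels) -> float:
    """Exact permutation p over every distinct relabelling (small n only)."""
    labels = np.asarray(labels)
    d2 = np.asarray(dm) ** 2
    n = len(labels)
    f_obs = permanova_f(d2, labels)
    groups, counts = np.unique(labels, return_counts=True)
    assert len(groups) == 2, "oracle supports two groups"
    k = counts[0]
    hits = total = 0
    for subset in combinations(range(n), k):
        perm = np.full(n, groups[1], dtype=object)
        perm[list(subset)] = groups[0]
        f = permanova_f(d2, perm)
        total += 1
        if f >= f_obs - 1e-12:
            hits += 1
    return hits / total


def ranksum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all rank splits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:n].sum()
    mean = n * (n + m + 1) / 2
    hits = total = 0
    for subset in combinations(range(n + m), n):
        s = ranks[list(subset)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return hits / total


def kruskal_h_from_ranks(values, labels) -> float:
    """Tie-corrected H via the rank sum-of-squares identity
    H = (N-1) * SSB(ranks) / SST(ranks)."""
    from scipy.stats import rankdata

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    r = rankdata(values)
    n = len(r)
    rbar = r.mean()
    sst = ((r - rbar) ** 2).sum()
    if sst == 0:
        return 0.0
    ssb = sum(
        len(r[labels == g]) * (r[labels == g].mean() - rbar) ** 2
        for g in np.unique(labels)
    )
    return (n - 1) * ssb / sst


def auc_concordance(pos, neg) -> float:
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))
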