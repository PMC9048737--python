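"""Alpha/beta diversity, ordination and PERMANOVA.

Alpha diversity is the Shannon index (base-2 entropy of the composition by
default) and Faith's phylogenetic diversity in its "whole tree" reading,
i.e. including the branches back to the root. Beta diversity is the UniFrac
distance (unweighted, or weighted with optional normalization), ordinated by
principal coordinates analysis and tested by PERMANOVA.

Faith's PD, UniFrac, PCoA and PERMANOVA are computed with scikit-bio; this
module owns validation, the result types, and the DataFrame-centric surface
used by the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac
from skbio.stats import distance as skbio_distance
from skbio.stats.ordination import pcoa as _skbio_pcoa


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # non-increasing, may include negatives
    proportion_explained: np.ndarray  # over positive eigenvalues only


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy -sum p_i log_base p_i over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon index of an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def _check_taxa_in_tree(taxa, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")


def faith_pd(counts, taxa, tree: TreeNode) -> float:
    """Total branch length spanned by the observed taxa, root included.

    Empty samples return 0 by convention.
    """
    c = np.asarray(counts, dtype=float)
    _check_taxa_in_tree(taxa, tree)
    if c.sum() == 0:
        return 0.0
    return float(_skbio_faith_pd(c, taxa, tree))


def unifrac(
    a, b, taxa, tree: TreeNode, weighted: bool = False, normalized: bool = True
) -> float:
    """UniFrac distance between two samples over a shared taxon list.

    Unweighted: unique branch length / union branch length over the two
    samples' descendant sets. Weighted: branch-length-weighted difference of
    relative-abundance mass, normalized by default so the result is in [0,1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_taxa_in_tree(taxa, tree)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("UniFrac is undefined for an empty sample")
    if weighted:
        return float(weighted_unifrac(a, b, taxa, tree, normalized=normalized))
    return float(unweighted_unifrac(a, b, taxa, tree))


def pairwise_distances(
    table: pd.DataFrame,
    tree: TreeNode,
    metric: str = "unweighted_unifrac",
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs UniFrac over a taxa-by-samples table."""
    if metric not in ("unweighted_unifrac", "weighted_unifrac"):
        raise ValueError(f"unknown metric {metric!r}")
    _check_taxa_in_tree(table.index, tree)
    counts = table.to_numpy().T  # skbio wants samples x taxa
    kwargs = {"normalized": normalized} if metric == "weighted_unifrac" else {}
    return beta_diversity(
        metric, counts, ids=list(table.columns), taxa=list(table.index),
        tree=tree, **kwargs,
    )


def alpha_diversity_frame(table: pd.DataFrame, tree: TreeNode, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon and Faith's PD, as one tidy frame."""
    return pd.DataFrame(
        {
            "shannon": [shannon(table[s], base=base) for s in table.columns],
            "faith_pd": [faith_pd(table[s], list(table.index), tree) for s in table.columns],
        },
        index=pd.Index(table.columns, name="sample_id"),
    )


def pcoa(dm: DistanceMatrix, cailliez: bool = False) -> OrdinationResult:
    """Principal coordinates of a distance matrix (Gower double-centering).

    Negative eigenvalues are reported but excluded from the
    proportion-explained denominator; no correction is applied unless the
    Cailliez additive constant is requested.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # raises on asymmetry
    method = "eigh"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # "all dimensions" notice
        res = _skbio_pcoa(dm, method=method, dimensions=0, warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    if cailliez and (eig < -1e-12).any():
        # additive constant: smallest c making d_ij + c Euclidean
        c = _cailliez_constant(dm.data)
        d = dm.data + c
        np.fill_diagonal(d, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = _skbio_pcoa(DistanceMatrix(d, dm.ids), method=method,
                              dimensions=0, warn_neg_eigval=False)
        eig = res.eigvals.to_numpy()
    pos = eig[eig > 0]
    prop = np.where(eig > 0, eig / pos.sum(), 0.0) if pos.size else np.zeros_like(eig)
    coords = res.samples.copy()
    coords.index = pd.Index(dm.ids, name="sample_id")
    return OrdinationResult(coordinates=coords, eigenvalues=eig, proportion_explained=prop)


def _cailliez_constant(d: np.ndarray) -> float:
    n = d.shape[0]
    d2 = d**2
    I = np.eye(n)
    J = I - np.ones((n, n)) / n
    del1 = -0.5 * J @ d2 @ J
    del2 = -0.5 * J @ d @ J
    upper = np.hstack([np.zeros((n, n)), 2 * del1])
    lower = np.hstack([-I, -4 * del2])
    eigs = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(max(np.real(eigs).max(), 0.0))


def permanova(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA (distance-based pseudo-F with a label-permutation
    null); p uses the +1 convention in numerator and denominator."""
    groups = pd.Series(np.asarray(groups), index=dm.ids)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    res = skbio_distance.permanova(
        dm, groups.to_numpy(), permutations=n_permutations, seed=seed
    )
    return PermanovaResult(
        pseudo_f=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_permutations,
        seed=seed,
    )


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis(
        "sample_id"
    ).to_csv(path, sep="\t", float_format="%.10g")
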