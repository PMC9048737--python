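"""Count-table, taxonomy, metadata and tree I/O plus basic table transforms.

Conventions
-----------
* Count tables are pandas DataFrames with taxa as rows and samples as
  columns (the usual amplicon orientation on disk), integer valued.
* Taxonomy is a pandas Series mapping ``taxon_id`` to a GreenGenes-style
  lineage string ``k__...;p__...;c__...;o__...;f__...;g__...;s__...``;
  missing ranks are allowed only as a trailing suffix.
* Metadata is a DataFrame indexed by ``sample_id`` with at least a
  ``group`` column drawn from {FRI, FH, HC}; extra columns (serum
  markers, subgroup flags) are preserved untouched.
* Trees are :class:`skbio.TreeNode` with branch lengths.

All readers validate hard and raise :class:`FeatureTableError` naming the
offending record; they never silently coerce inconsistent inputs.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

GROUP_LABELS = ("FRI", "FH", "HC")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FeatureTableError(ValueError):
    """Malformed or inconsistent feature-table input."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read a taxa-by-samples count TSV (first column ``taxon_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "taxon_id":
        raise FeatureTableError(
            f"count table must have 'taxon_id' as first column, got {df.columns[0]!r}"
        )
    df = df.set_index("taxon_id")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FeatureTableError(f"duplicate taxon ids in count table: {dup}")
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if dup:
        raise FeatureTableError(f"duplicate sample ids in count table: {dup}")
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise FeatureTableError("count table contains non-numeric cells")
    if (counts < 0).any():
        bad = df.index[(counts < 0).any(axis=1)].tolist()
        raise FeatureTableError(f"negative counts for taxa: {bad}")
    if not np.allclose(counts, np.round(counts)):
        raise FeatureTableError("count table contains non-integer values")
    out = df.astype(np.int64)
    validate_table(out)
    return out


def write_table(table: pd.DataFrame, path) -> None:
    table.rename_axis("taxon_id").to_csv(path, sep="\t")


def validate_table(table: pd.DataFrame) -> None:
    """Check the in-memory invariants of a count table."""
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise FeatureTableError("duplicate taxon or sample ids")
    if (table.to_numpy() < 0).any():
        raise FeatureTableError("negative counts")
    empty = table.columns[table.sum(axis=0) == 0].tolist()
    if empty:
        raise FeatureTableError(f"all-zero sample columns: {empty}")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise FeatureTableError(f"duplicate sample ids in metadata: {dup}")
    if "group" not in meta.columns:
        raise FeatureTableError("metadata must contain a 'group' column")
    bad = sorted(set(meta["group"]) - set(GROUP_LABELS))
    if bad:
        raise FeatureTableError(f"unknown group labels {bad}; expected {GROUP_LABELS}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["taxon_id", "lineage"]:
        raise FeatureTableError("taxonomy TSV must have columns taxon_id, lineage")
    tax = df.set_index("taxon_id")["lineage"]
    if tax.index.duplicated().any():
        dup = tax.index[tax.index.duplicated()].unique().tolist()
        raise FeatureTableError(f"duplicate taxon ids in taxonomy: {dup}")
    for tid, lineage in tax.items():
        validate_lineage(tid, lineage)
    return tax


def validate_lineage(taxon_id: str, lineage: str) -> None:
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) > 7:
        raise FeatureTableError(f"taxon {taxon_id}: lineage has more than 7 ranks")
    seen_missing = False
    for part, prefix in zip(parts, RANK_PREFIXES):
        if not part.startswith(prefix):
            raise FeatureTableError(
                f"taxon {taxon_id}: rank {part!r} lacks prefix {prefix!r}"
            )
        name = part[len(prefix):]
        if name == "":
            seen_missing = True
        elif seen_missing:
            raise FeatureTableError(
                f"taxon {taxon_id}: named rank {part!r} follows a missing rank"
            )


def write_taxonomy(taxonomy: pd.Series, path) -> None:
    taxonomy.rename("lineage").rename_axis("taxon_id").to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FeatureTableError(f"malformed Newick in {path}: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FeatureTableError(
                f"tree edge above {node.name or '<internal>'} lacks a branch length"
            )
        if node.length < 0:
            raise FeatureTableError(f"negative branch length above {node.name}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def validate_ids(
    table: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    tree: TreeNode | None = None,
    taxonomy: pd.Series | None = None,
) -> None:
    """Cross-validate identifier sets; raise listing every mismatch found."""
    problems = []
    if metadata is not None:
        missing = sorted(set(table.columns) - set(metadata.index))
        if missing:
            problems.append(f"samples missing from metadata: {missing}")
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = sorted(set(table.index) - tips)
        if missing:
            problems.append(f"taxa missing from tree: {missing}")
    if taxonomy is not None:
        missing = sorted(set(table.index) - set(taxonomy.index))
        if missing:
            problems.append(f"taxa missing from taxonomy: {missing}")
    if problems:
        raise FeatureTableError("; ".join(problems))


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def lineage_prefix(lineage: str, rank: str) -> tuple[str, ...]:
    depth = RANKS.index(rank) + 1
    parts = [p.strip() for p in lineage.split(";")][:depth]
    parts += [""] * (depth - len(parts))
    return tuple(p[3:] if len(p) >= 3 else "" for p in parts)


def collapse_to_rank(table: pd.DataFrame, taxonomy: pd.Series, rank: str) -> pd.DataFrame:
    """Sum rows sharing the lineage prefix down to ``rank``.

    Taxa whose lineage is unnamed at ``rank`` are pooled per parent into an
    ``unclassified_<parent>`` row. Column sums are preserved exactly.
    """
    if rank not in RANKS:
        raise FeatureTableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    validate_ids(table, taxonomy=taxonomy)
    keys: dict[str, tuple] = {}
    for tid in table.index:
        keys[tid] = lineage_prefix(taxonomy[tid], rank)

    def label_for(prefix: tuple[str, ...]) -> str:
        if prefix[-1]:
            return prefix[-1]
        parent = next((p for p in reversed(prefix[:-1]) if p), "root")
        return f"unclassified_{parent}"

    key_strings = pd.Series([";".join(keys[t]) for t in table.index], index=table.index)
    grouped = table.groupby(key_strings, sort=False).sum()
    grouped.index = pd.Index([tuple(k.split(";")) for k in grouped.index])
    labels = [label_for(p) for p in grouped.index]
    # disambiguate homonymous groups from different parents
    lab = pd.Series(labels)
    for name in lab[lab.duplicated()].unique():
        idx = lab.index[lab == name]
        for i in idx:
            parent = next((p for p in reversed(grouped.index[i][:-1]) if p), "root")
            lab.iloc[i] = f"{name} ({parent})"
    grouped.index = pd.Index(lab, name="taxon_id")
    return grouped


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total; columns sum to 1."""
    totals = table.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise FeatureTableError(f"cannot normalize all-zero samples: {zero}")
    return table / totals


def abundance_prevalence_filter(
    rel: pd.DataFrame, min_rel: float = 1e-4, min_prev: float = 0.2
) -> pd.DataFrame:
    """Keep taxa reaching relative abundance >= ``min_rel`` in >= ``min_prev``
    of samples (both boundaries inclusive); no renormalization."""
    if not 0 < min_rel < 1:
        raise FeatureTableError("min_rel must lie in (0, 1)")
    if not 0 < min_prev <= 1:
        raise FeatureTableError("min_prev must lie in (0, 1]")
    prevalence = (rel >= min_rel).mean(axis=1)
    kept = rel.loc[prevalence >= min_prev]
    if kept.empty:
        warnings.warn("abundance/prevalence filter removed every taxon", stacklevel=2)
    return kept


def subsample_even_depth(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Optional rarefaction to an even depth; samples shallower than ``depth``
    are dropped. Off by default throughout the pipeline."""
    rng = np.random.default_rng(seed)
    keep = table.columns[table.sum(axis=0) >= depth]
    out = {}
    for s in keep:
        col = table[s].to_numpy()
        pool = np.repeat(np.arange(len(col)), col)
        picks = rng.choice(pool, size=depth, replace=False)
        out[s] = np.bincount(picks, minlength=len(col))
    return pd.DataFrame(out, index=table.index, dtype=np.int64)
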