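"""Synthetic case-control microbiome datasets with planted ground truth.

The generator emulates the statistical structure of a three-group
fecal-microbiome case-control study (infected cases ``FRI``, fracture-healed
controls ``FH``, healthy controls ``HC``): Dirichlet-multinomial ASV counts
with group-specific fold changes on a small set of signature genera, reduced
richness in the case group, and serum inflammatory markers coupled to
planted taxa through a Gaussian copula on ranks so that target Spearman
correlations are hit approximately.

Everything is driven by a single integer seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from . import feature_table as ft

CASE_GROUP = "FRI"

#: the 4 case-enriched / 10 control-enriched genera the dysbiosis signature
#: is built from (used as planted ground truth by the default scenario)
CASE_ENRICHED_GENERA = ("Escherichia", "Veillonella", "Streptococcus", "Actinomyces")
CONTROL_ENRICHED_GENERA = (
    "Roseburia",
    "Parabacteroides",
    "Desulfovibrio",
    "Blautia",
    "Coprococcus",
    "Prevotella",
    "SMB53",
    "Phascolarctobacterium",
    "Dialister",
    "Anaerostipes",
)

#: serum markers linked to planted taxa: (marker, planted ASV, target rho).
#: Inflammatory markers rise with case-enriched taxa and fall with
#: control-enriched (short-chain-fatty-acid producing) taxa.
DEFAULT_MARKER_LINKS = (
    ("NEU", "asv_Escherichia", 0.5),
    ("ESR", "asv_Escherichia", 0.6),
    ("CRP", "asv_Escherichia", 0.6),
    ("SAA", "asv_Streptococcus", 0.5),
    ("WBC", "asv_Veillonella", 0.4),
    ("PCT", "asv_Actinomyces", 0.4),
    ("IL-6", "asv_Roseburia", -0.5),
    ("TNF-a", "asv_Blautia", -0.4),
    ("UA", "asv_Prevotella", -0.3),
    ("VD", "asv_Coprococcus", -0.4),
    ("Glu", "asv_Dialister", -0.3),
)


def _default_planted(log2_fc: float = 3.0) -> tuple[tuple[str, str, float], ...]:
    enr = tuple((f"asv_{g}", CASE_GROUP, log2_fc) for g in CASE_ENRICHED_GENERA)
    dep = tuple((f"asv_{g}", CASE_GROUP, -log2_fc) for g in CONTROL_ENRICHED_GENERA)
    return enr + dep


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the modeled cohort: group sizes 20/18/12, 120 ASVs,
    +/-3 log2 fold change planted on the 4 case-enriched and 10
    control-enriched signature genera, a quarter of background taxa absent
    from the case group, and serum markers rank-coupled to planted taxa.
    """

    n_per_group: dict = field(default_factory=lambda: {"FRI": 20, "FH": 18, "HC": 12})
    n_taxa: int = 120
    library_size_mean: float = 20000.0
    library_size_dispersion: float = 5.0  # negative-binomial size parameter
    base_concentration: float = 100.0  # total Dirichlet concentration
    planted_effects: tuple = field(default_factory=_default_planted)
    richness_deficit_frac: float = 0.25
    marker_links: tuple = field(default_factory=lambda: DEFAULT_MARKER_LINKS)
    age_range: tuple = (18, 70)
    male_frac: float = 37 / 50  # pooled cohort sex ratio 37:13
    sinus_pus_frac: float = 16 / 20  # cases with sinus tract or visible pus
    seed: int = 0

    def validate(self, taxa: list[str] | None = None) -> None:
        for tid, grp, fc in self.planted_effects:
            if grp not in ft.GROUP_LABELS:
                raise ValueError(f"planted effect on unknown group {grp!r}")
            if not np.isfinite(fc):
                raise ValueError(f"non-finite fold change for {tid}")
            if taxa is not None and tid not in taxa:
                raise ValueError(f"planted taxon {tid!r} not among tree leaves")
        for grp in self.n_per_group:
            if grp not in ft.GROUP_LABELS:
                raise ValueError(f"unknown group label {grp!r}")
        if not 0 <= self.richness_deficit_frac < 1:
            raise ValueError("richness_deficit_frac must lie in [0, 1)")
        for marker, tid, rho in self.marker_links:
            if not -1 < rho < 1:
                raise ValueError(f"marker link {marker}->{tid}: |rho| must be < 1")
            if taxa is not None and tid not in taxa:
                raise ValueError(f"marker-linked taxon {tid!r} not among tree leaves")


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects restated as the sets the analysis should recover."""

    true_enriched: frozenset
    true_depleted: frozenset
    true_marker_correlation_signs: dict

    def __post_init__(self):
        if self.true_enriched & self.true_depleted:
            raise ValueError("a taxon cannot be both enriched and depleted")


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def taxon_names(n_taxa: int) -> list[str]:
    """ASV identifiers: one ASV per signature genus, then numbered fillers."""
    names = [f"asv_{g}" for g in CASE_ENRICHED_GENERA + CONTROL_ENRICHED_GENERA]
    names += [f"asv_{i:04d}" for i in range(1, max(0, n_taxa - len(names)) + 1)]
    return names[:n_taxa]


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random coalescent-style rooted binary tree over ``n_taxa`` labelled
    leaves with exponential branch lengths; deterministic given ``seed``."""
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name) for name in taxon_names(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        for child in (left, right):
            child.length = float(rng.exponential(0.1)) + 1e-3
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def simulate_taxonomy(taxa: list[str]) -> pd.Series:
    """Seven-rank GreenGenes-style lineages.

    Signature ASVs carry their genus name; filler ASVs get numbered genera,
    with every fifth pair of fillers sharing one genus so that collapsing to
    genus rank has real merging to do. A handful of fillers drop the genus
    rank entirely to exercise the ``unclassified_<parent>`` pooling path.
    """
    signature = set(CASE_ENRICHED_GENERA + CONTROL_ENRICHED_GENERA)
    families = ("Lachnospiraceae", "Ruminococcaceae", "Bacteroidaceae",
                "Veillonellaceae", "Prevotellaceae")
    lineages = {}
    filler_idx = 0
    for tid in taxa:
        stem = tid.removeprefix("asv_")
        if stem in signature:
            genus = stem
            fam = "Enterobacteriaceae" if stem == "Escherichia" else families[
                len(stem) % len(families)]
        else:
            filler_idx += 1
            if filler_idx % 10 == 0:  # merge with the previous filler's genus
                genus = f"genus{filler_idx - 1:04d}"
            elif filler_idx % 10 == 7:  # genus rank missing
                genus = ""
            else:
                genus = f"genus{filler_idx:04d}"
            fam = families[filler_idx % len(families)]
        parts = [
            "k__Bacteria",
            "p__Firmicutes",
            "c__Clostridia",
            "o__Clostridiales",
            f"f__{fam}",
            f"g__{genus}",
        ]
        if genus == "":  # missing ranks only as a suffix
            parts = parts[:5] + ["g__"]
        lineages[tid] = ";".join(parts + ["s__"]) if genus else ";".join(parts)
    return pd.Series(lineages, name="lineage").rename_axis("taxon_id")


# ---------------------------------------------------------------------------
# counts, metadata, markers
# ---------------------------------------------------------------------------

def _base_concentrations(taxa: list[str], planted: set[str], cfg, rng) -> np.ndarray:
    """Per-taxon Dirichlet parameters summing to ``base_concentration``.

    Background taxa get long-tailed lognormal weights; planted taxa draw from
    a tighter, higher lognormal so signature genera are common enough to
    survive the abundance/prevalence filter, as the real signature genera are.
    """
    logw = rng.normal(0.0, 1.5, size=len(taxa))
    for k, tid in enumerate(taxa):
        if tid in planted:
            logw[k] = rng.normal(1.0, 0.5)
    w = np.exp(logw)
    return cfg.base_concentration * w / w.sum()


def simulate_counts(
    config: SimulationConfig, tree: TreeNode
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a (counts, metadata, ground-truth) triple under ``config``.

    Per sample: library size ~ negative binomial, composition ~ Dirichlet
    with group-specific concentrations (base x 2^log2FC on planted pairs;
    a ``richness_deficit_frac`` share of background taxa zeroed in the case
    group), counts ~ multinomial. Serum markers are monotone transforms of a
    planted taxon's relative-abundance normal scores plus Gaussian noise
    calibrated to the target Spearman rho.
    """
    taxa = [t.name for t in tree.tips()]
    if len(set(taxa)) != len(taxa):
        raise ValueError("tree has duplicate leaf names")
    config.validate(taxa)
    rng = np.random.default_rng(config.seed)

    planted_ids = {tid for tid, _, _ in config.planted_effects}
    base = _base_concentrations(taxa, planted_ids, config, rng)
    tindex = {t: k for k, t in enumerate(taxa)}

    group_alpha = {}
    for grp in config.n_per_group:
        alpha = base.copy()
        for tid, g, fc in config.planted_effects:
            if g == grp:
                alpha[tindex[tid]] *= 2.0**fc
        group_alpha[grp] = alpha
    # richness deficit: background taxa absent from the case community
    background = [t for t in taxa if t not in planted_ids]
    n_drop = int(np.floor(config.richness_deficit_frac * len(background)))
    if n_drop and CASE_GROUP in group_alpha:
        drop = rng.choice(len(background), size=n_drop, replace=False)
        for k in drop:
            group_alpha[CASE_GROUP][tindex[background[k]]] = 0.0

    sample_ids, groups, columns = [], [], []
    nb_size = config.library_size_dispersion
    nb_p = nb_size / (nb_size + config.library_size_mean)
    for grp, n in config.n_per_group.items():
        alpha = group_alpha[grp]
        live = alpha > 0
        for i in range(1, n + 1):
            depth = int(rng.negative_binomial(nb_size, nb_p)) + 1
            p = np.zeros(len(taxa))
            p[live] = rng.dirichlet(alpha[live])
            counts = rng.multinomial(depth, p)
            sample_ids.append(f"{grp}_{i:02d}")
            groups.append(grp)
            columns.append(counts)
    table = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(taxa, name="taxon_id"),
        columns=sample_ids, dtype=np.int64,
    )

    n_samples = len(sample_ids)
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["group"] = groups
    meta["age"] = rng.integers(config.age_range[0], config.age_range[1] + 1, n_samples)
    meta["sex"] = np.where(rng.random(n_samples) < config.male_frac, "M", "F")
    is_case = meta["group"] == CASE_GROUP
    sinus = np.where(rng.random(n_samples) < config.sinus_pus_frac, "yes", "no")
    meta["sinus_pus"] = np.where(is_case, sinus, "n/a")

    rel = table / table.sum(axis=0)
    for marker, tid, rho in config.marker_links:
        x = rel.loc[tid].to_numpy()
        ranks = stats.rankdata(x)
        z = stats.norm.ppf((ranks - 0.5) / n_samples)
        r = 2.0 * np.sin(np.pi * rho / 6.0)  # Pearson r giving Spearman rho
        latent = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n_samples)
        meta[marker] = np.round(np.exp(1.0 + 0.8 * latent), 4)  # lognormal scale

    truth = GroundTruth(
        true_enriched=frozenset(
            tid for tid, g, fc in config.planted_effects
            if (g == CASE_GROUP) == (fc > 0)
        ),
        true_depleted=frozenset(
            tid for tid, g, fc in config.planted_effects
            if (g == CASE_GROUP) == (fc < 0)
        ),
        true_marker_correlation_signs={
            (m, t): int(np.sign(rho)) for m, t, rho in config.marker_links
        },
    )
    return table, meta, truth


def write_dataset(table, metadata, tree, taxonomy, out_dir) -> dict:
    """Write counts/metadata/tree/taxonomy under ``out_dir``; return the
    manifest of paths. Round-trips exactly through the feature_table readers."""
    ft.validate_ids(table, metadata=metadata, tree=tree, taxonomy=taxonomy)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "tree": out / "tree.nwk",
        "taxonomy": out / "taxonomy.tsv",
    }
    ft.write_table(table, manifest["counts"])
    ft.write_metadata(metadata, manifest["metadata"])
    ft.write_tree(tree, manifest["tree"])
    ft.write_taxonomy(taxonomy, manifest["taxonomy"])
    return {k: str(v) for k, v in manifest.items()}


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: tree + taxonomy + counts/metadata/truth."""
    tree = simulate_tree(config.n_taxa, config.seed)
    taxonomy = simulate_taxonomy([t.name for t in tree.tips()])
    table, meta, truth = simulate_counts(config, tree)
    return table, meta, tree, taxonomy, truth
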