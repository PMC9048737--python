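"""End-to-end orchestration: simulate -> filter -> diversity -> biomarkers
-> dysbiosis -> evaluate, with a checksum manifest for reproducibility.

Each stage is an ordinary function over the library types so the numbered
scripts under ``analysis/`` (and the tests) can drive any single stage;
:func:`run` chains them, writes every intermediate table under the run
directory, and records a manifest of the config hash and the SHA-256 of
every output. Reruns with an identical config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers, diversity, evaluate, feature_table as ft, synthetic

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a full pipeline run.

    ``seed`` drives every stochastic stage; per-stage seeds are derived from
    it with fixed offsets so stages stay independently reproducible.
    """

    seed: int = 0
    out_dir: str = "results/run"
    simulation: synthetic.SimulationConfig | None = None
    inputs: dict | None = None  # paths: counts, metadata, tree, taxonomy
    min_rel: float = 1e-4
    min_prev: float = 0.2
    shannon_base: float = 2.0
    beta_metric: str = "unweighted_unifrac"
    unifrac_normalized: bool = True
    n_permutations: int = 999
    alpha: float = 0.05
    lda_threshold: float = 2.0
    n_boot: int = 30
    subsample_frac: float = 2 / 3
    glm_family: str = "negative-binomial"
    signature_mode: str = "glm-union"
    manual_case: tuple = ()
    manual_control: tuple = ()
    pseudocount: float = 1e-6

    def stage_seed(self, offset: int) -> int:
        return (self.seed * 1000 + offset) % (2**31 - 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["planted_effects"] = [list(t) for t in sim["planted_effects"]]
            sim["marker_links"] = [list(t) for t in sim["marker_links"]]
            sim["age_range"] = list(sim["age_range"])
            d["simulation"] = sim
        d["manual_case"] = list(self.manual_case)
        d["manual_control"] = list(self.manual_control)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            sim = dict(sim)
            sim["planted_effects"] = tuple(tuple(t) for t in sim["planted_effects"])
            sim["marker_links"] = tuple(tuple(t) for t in sim["marker_links"])
            sim["age_range"] = tuple(sim["age_range"])
            d["simulation"] = synthetic.SimulationConfig(**sim)
        d["manual_case"] = tuple(d.get("manual_case", ()))
        d["manual_control"] = tuple(d.get("manual_control", ()))
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land is not a parameter
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_inputs(config: RunConfig, out: Path) -> dict:
    """Simulate (or load) the dataset; returns table/metadata/tree/taxonomy."""
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.stage_seed(1))
        table, meta, tree, taxonomy, truth = synthetic.simulate_dataset(sim)
        synthetic.write_dataset(table, meta, tree, taxonomy, out / "dataset")
    elif config.inputs is not None:
        table = ft.read_table(config.inputs["counts"])
        meta = ft.read_metadata(config.inputs["metadata"])
        tree = ft.read_tree(config.inputs["tree"])
        taxonomy = ft.read_taxonomy(config.inputs["taxonomy"])
        truth = None
    else:
        raise ValueError("config needs either a simulation block or input paths")
    ft.validate_ids(table, metadata=meta, tree=tree, taxonomy=taxonomy)
    return {"table": table, "metadata": meta, "tree": tree,
            "taxonomy": taxonomy, "truth": truth}


def stage_filter(config: RunConfig, data: dict, out: Path) -> dict:
    """Collapse to genus, convert to relative abundance, apply the
    abundance/prevalence filter."""
    genus = ft.collapse_to_rank(data["table"], data["taxonomy"], "genus")
    genus_rel = ft.relative_abundance(genus)
    kept = ft.abundance_prevalence_filter(genus_rel, config.min_rel, config.min_prev)
    _write_tsv(genus, out / "genus_counts.tsv")
    _write_tsv(kept, out / "genus_rel_filtered.tsv")
    return {"genus": genus, "genus_rel": genus_rel, "genus_rel_filtered": kept}


def stage_diversity(config: RunConfig, data: dict, out: Path) -> dict:
    """Alpha diversity, UniFrac distances, PCoA, PERMANOVA (ASV level)."""
    table, tree = data["table"], data["tree"]
    groups = data["metadata"]["group"]
    alpha = diversity.alpha_diversity_frame(table, tree, base=config.shannon_base)
    arg = (
        ft.relative_abundance(table)
        if config.beta_metric == "weighted_unifrac"
        else table
    )
    dm = diversity.pairwise_distances(
        arg, tree, metric=config.beta_metric, normalized=config.unifrac_normalized
    )
    ordination = diversity.pcoa(dm)
    perm = diversity.permanova(
        dm, groups.loc[list(dm.ids)], n_permutations=config.n_permutations,
        seed=config.stage_seed(2),
    )
    _write_tsv(alpha, out / "alpha_diversity.tsv")
    diversity.write_distance_matrix(dm, out / "beta_distances.tsv")
    _write_tsv(ordination.coordinates, out / "pcoa_coordinates.tsv")
    _write_tsv(
        pd.DataFrame(
            {
                "eigenvalue": ordination.eigenvalues,
                "proportion_explained": ordination.proportion_explained,
            }
        ).rename_axis("axis"),
        out / "pcoa_eigenvalues.tsv",
    )
    (out / "permanova.json").write_text(
        json.dumps(dataclasses.asdict(perm), indent=2, sort_keys=True)
    )
    return {"alpha": alpha, "dm": dm, "ordination": ordination, "permanova": perm}


def stage_biomarkers(config: RunConfig, data: dict, filtered: dict, out: Path) -> dict:
    """LEfSe scores, GLM differential abundance, signature construction."""
    rel = filtered["genus_rel_filtered"]
    meta = data["metadata"]
    groups = meta["group"].loc[rel.columns]
    lefse = biomarkers.lda_effect_size(
        rel, groups, alpha=config.alpha, lda_threshold=config.lda_threshold,
        n_boot=config.n_boot, subsample_frac=config.subsample_frac,
        seed=config.stage_seed(3),
    )
    genus_counts = filtered["genus"].loc[rel.index]
    totals = filtered["genus"].sum(axis=0)
    glm_frames = [
        biomarkers.glm_differential(
            genus_counts, meta, comp, family=config.glm_family, totals=totals
        )
        for comp in biomarkers.COMPARISONS
    ]
    glm_all = pd.concat(glm_frames)
    if config.signature_mode == "manual":
        sig = biomarkers.build_signature(
            "manual", rel=filtered["genus_rel"],
            manual_case=config.manual_case, manual_control=config.manual_control,
        )
    elif config.signature_mode == "lefse":
        sig = biomarkers.build_signature("lefse", lefse=lefse)
    else:
        sig = biomarkers.build_signature(
            "glm-union", rel=rel, groups=groups, glm=glm_all, alpha=config.alpha
        )
    _write_tsv(lefse, out / "lefse_scores.tsv")
    _write_tsv(glm_all, out / "glm_differential.tsv")
    (out / "signature.json").write_text(
        json.dumps(
            {
                "enriched_in_case": sorted(sig.enriched_in_case),
                "enriched_in_control": sorted(sig.enriched_in_control),
                "provenance": sig.provenance,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {"lefse": lefse, "glm": glm_all, "signature": sig}


def stage_dysbiosis(config: RunConfig, data: dict, filtered: dict, sig, out: Path) -> dict:
    di = evaluate.dysbiosis_index(
        filtered["genus_rel"], sig, pseudocount=config.pseudocount
    )
    frame = pd.DataFrame(
        {
            "dysbiosis_index": di,
            "log10_di": np.log10(di),
            "group": data["metadata"]["group"].loc[di.index],
        }
    ).rename_axis("sample_id")
    _write_tsv(frame, out / "dysbiosis_index.tsv")
    return {"di": di, "di_frame": frame}


def stage_evaluate(config: RunConfig, data: dict, filtered: dict, sig, di, out: Path) -> dict:
    """Group tests on the index, ROC/AUC, odds ratios, marker correlations."""
    meta = data["metadata"]
    groups = meta["group"].loc[di.index]
    summary: dict = {}
    summary["di_kruskal"] = evaluate.compare_groups(di, groups, "kruskal")
    for a, b in (("FRI", "FH"), ("FRI", "HC"), ("FH", "HC")):
        mask = groups.isin([a, b])
        summary[f"di_wilcoxon_{a}_vs_{b}"] = evaluate.compare_groups(
            di[mask], groups[mask], "wilcoxon"
        )
    for ctrl in ("HC", "FH"):
        mask = groups.isin(["FRI", ctrl])
        roc = evaluate.roc_auc(di[mask], groups[mask], positive="FRI")
        summary[f"di_auc_FRI_vs_{ctrl}"] = roc.auc
        pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivities,
                "specificity": roc.specificities,
            }
        ).to_csv(out / f"roc_di_FRI_vs_{ctrl}.tsv", sep="\t",
                 index=False, float_format=FLOAT_FMT)
        sig_rel = filtered["genus_rel"].loc[
            sorted(sig.members & set(filtered["genus_rel"].index))
        ]
        mv = evaluate.multivariate_auc(
            sig_rel.loc[:, mask[mask].index], groups[mask], positive="FRI",
            seed=config.stage_seed(4), pseudocount=config.pseudocount,
        )
        summary[f"composition_auc_FRI_vs_{ctrl}"] = mv.auc

    marker_cols = [c for c in meta.columns
                   if c not in ("group", "age", "sex", "sinus_pus")]
    if marker_cols:
        ors = evaluate.odds_ratios(meta, marker_cols)
        _write_tsv(ors, out / "odds_ratios.tsv")
        corr = evaluate.marker_taxon_correlations(
            filtered["genus_rel_filtered"], meta, marker_cols
        )
        corr.to_csv(out / "marker_taxon_correlations.tsv", sep="\t",
                    index=False, float_format=FLOAT_FMT)
        best = {}
        for m in marker_cols:
            fri_fh = meta["group"].isin(["FRI", "FH"])
            ids = meta.index[fri_fh]
            best[m] = evaluate.roc_auc(
                meta.loc[ids, m].astype(float), meta.loc[ids, "group"], positive="FRI"
            ).auc
        summary["serum_marker_aucs_FRI_vs_FH"] = best
        summary["best_serum_marker_auc_FRI_vs_FH"] = max(best.values())
    (out / "evaluation_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    return {"summary": summary}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run(config: RunConfig) -> dict:
    """Execute every stage in dependency order and write the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    bundle: dict = {}
    stages = []

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception:
            logger.error("stage %s failed", name)
            raise
        logger.info("stage=%s seed=%d wall=%.2fs", name, config.seed,
                    time.perf_counter() - t0)
        stages.append(name)
        return result

    data = timed("inputs", stage_inputs, config, out)
    bundle.update(data)
    filtered = timed("filter", stage_filter, config, data, out)
    bundle.update(filtered)
    bundle.update(timed("diversity", stage_diversity, config, data, out))
    marks = timed("biomarkers", stage_biomarkers, config, data, filtered, out)
    bundle.update(marks)
    dys = timed("dysbiosis", stage_dysbiosis, config, data, filtered,
                marks["signature"], out)
    bundle.update(dys)
    bundle.update(timed("evaluate", stage_evaluate, config, data, filtered,
                        marks["signature"], dys["di"], out))

    files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "config.json")
    )
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
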