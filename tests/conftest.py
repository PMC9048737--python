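import dataclasses
import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from dysbiom import feature_table as ft
from dysbiom import synthetic

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def toy_tree() -> TreeNode:
    return TreeNode.read(io.StringIO(TOY_NEWICK))


@pytest.fixture(scope="session")
def study_dataset():
    """One study-conditions dataset (group sizes 20/18/12, planted signature)."""
    cfg = synthetic.SimulationConfig(seed=0)
    table, meta, tree, taxonomy, truth = synthetic.simulate_dataset(cfg)
    return {"config": cfg, "table": table, "metadata": meta, "tree": tree,
            "taxonomy": taxonomy, "truth": truth}


@pytest.fixture(scope="session")
def study_genus(study_dataset):
    genus = ft.collapse_to_rank(
        study_dataset["table"], study_dataset["taxonomy"], "genus"
    )
    rel = ft.relative_abundance(genus)
    return {"genus": genus, "rel": rel,
            "filtered": ft.abundance_prevalence_filter(rel)}


def planted_only_config(seed: int) -> synthetic.SimulationConfig:
    """Study conditions with only the 14 fold-change effects planted (no
    richness deficit), so ground truth is exactly the signature genera."""
    return dataclasses.replace(
        synthetic.SimulationConfig(), seed=seed, richness_deficit_frac=0.0
    )


def null_config(seed: int, n_per_group=None, n_taxa: int = 30) -> synthetic.SimulationConfig:
    """No planted effects at all: every taxon follows the same composition."""
    return dataclasses.replace(
        synthetic.SimulationConfig(),
        seed=seed,
        planted_effects=(),
        marker_links=(),
        richness_deficit_frac=0.0,
        n_taxa=n_taxa,
        n_per_group=n_per_group or {"FRI": 7, "FH": 7, "HC": 6},
    )


def random_table(rng: np.random.Generator, n_taxa: int, n_samples: int) -> pd.DataFrame:
    counts = rng.integers(0, 50, size=(n_taxa, n_samples))
    counts[0] += 1  # keep every sample non-empty
    return pd.DataFrame(
        counts,
        index=pd.Index([f"t{i}" for i in range(n_taxa)], name="taxon_id"),
        columns=[f"s{j}" for j in range(n_samples)],
        dtype=np.int64,
    )
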