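"""Shared plumbing for the numbered analysis drivers.

Every driver is a pure function of ``--seed``: the dataset is re-simulated
deterministically, so the scripts can run in any order and always agree
with one another and with the written artifacts.
"""

import argparse
from pathlib import Path

from dysbiom import pipeline, synthetic


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    return ap.parse_args()


def make_config(seed: int, out: Path) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        seed=seed,
        out_dir=str(out),
        simulation=synthetic.SimulationConfig(),
        signature_mode="lefse",
    )


def prepare(cfg: pipeline.RunConfig, out: Path, with_filter: bool = False):
    out.mkdir(parents=True, exist_ok=True)
    data = pipeline.stage_inputs(cfg, out)
    if not with_filter:
        return data, None
    return data, pipeline.stage_filter(cfg, data, out)
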