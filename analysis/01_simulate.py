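"""Simulate the study cohort: three groups (20 infected cases, 18 healed
fracture controls, 12 healthy controls) of Dirichlet-multinomial ASV counts
with the 4 case-enriched / 10 control-enriched signature genera planted,
reduced richness in the case group, and rank-linked serum markers."""

from _common import make_config, parse_args, prepare


def main():
    args = parse_args(__doc__)
    cfg = make_config(args.seed, args.out)
    data, _ = prepare(cfg, args.out)
    table, meta, truth = data["table"], data["metadata"], data["truth"]
    print(f"dataset written under {args.out}/dataset")
    print(f"  {table.shape[0]} ASVs x {table.shape[1]} samples")
    print("  group sizes:", meta["group"].value_counts().to_dict())
    print("  planted enriched:", sorted(truth.true_enriched))
    print("  planted depleted:", sorted(truth.true_depleted))
    print("  median library size:", int(table.sum(axis=0).median()))


if __name__ == "__main__":
    main()
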