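"""Collapse the ASV table to genus rank, convert to relative abundance,
and apply the abundance/prevalence filter (keep genera reaching 0.01%
relative abundance in at least 20% of samples)."""

from _common import make_config, parse_args, prepare


def main():
    args = parse_args(__doc__)
    cfg = make_config(args.seed, args.out)
    _, filtered = prepare(cfg, args.out, with_filter=True)
    genus, kept = filtered["genus"], filtered["genus_rel_filtered"]
    print(f"{genus.shape[0]} genera after collapsing; "
          f"{kept.shape[0]} pass the abundance/prevalence filter")
    print(f"tables written: {args.out}/genus_counts.tsv, "
          f"{args.out}/genus_rel_filtered.tsv")


if __name__ == "__main__":
    main()
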