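"""Diversity profile: Shannon and Faith's PD per sample, unweighted
UniFrac distances, PCoA ordination, and a PERMANOVA test of group
separation."""

from _common import make_config, parse_args, prepare
from dysbiom import pipeline


def main():
    args = parse_args(__doc__)
    cfg = make_config(args.seed, args.out)
    data, _ = prepare(cfg, args.out)
    res = pipeline.stage_diversity(cfg, data, args.out)
    groups = data["metadata"]["group"]
    med = res["alpha"].groupby(groups).median()
    print("median alpha diversity per group:")
    print(med.to_string(float_format="%.3f"))
    perm = res["permanova"]
    print(f"PERMANOVA on unweighted UniFrac: pseudo-F={perm.pseudo_f:.2f}, "
          f"p={perm.p_value:.4g} ({perm.n_permutations} permutations)")
    prop = res["ordination"].proportion_explained[:2]
    print(f"PCoA axes 1-2 explain {100*prop[0]:.1f}% and {100*prop[1]:.1f}%")


if __name__ == "__main__":
    main()
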