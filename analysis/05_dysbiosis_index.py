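"""Dysbiosis index: per-sample ratio of case-enriched to control-enriched
relative-abundance mass under the discovered signature, with rank tests of
the group ordering."""

from _common import make_config, parse_args, prepare
from dysbiom import evaluate, pipeline


def main():
    args = parse_args(__doc__)
    cfg = make_config(args.seed, args.out)
    data, filtered = prepare(cfg, args.out, with_filter=True)
    marks = pipeline.stage_biomarkers(cfg, data, filtered, args.out)
    res = pipeline.stage_dysbiosis(cfg, data, filtered, marks["signature"], args.out)
    di, groups = res["di"], data["metadata"]["group"]
    med = di.groupby(groups).median()
    print("median dysbiosis index per group:")
    print(med.to_string(float_format="%.3f"))
    for a, b in (("FRI", "FH"), ("FRI", "HC"), ("FH", "HC")):
        mask = groups.isin([a, b])
        t = evaluate.compare_groups(di[mask], groups[mask], "wilcoxon")
        print(f"  {a} vs {b}: rank-sum p = {t['p']:.4g}")


if __name__ == "__main__":
    main()
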