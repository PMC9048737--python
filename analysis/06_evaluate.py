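"""Discrimination and marker analysis: ROC/AUC of the dysbiosis index and
of the signature composition (leave-pair-out logistic model), serum-marker
odds ratios, and Spearman marker-taxon correlations."""

import json

from _common import make_config, parse_args, prepare
from dysbiom import pipeline


def main():
    args = parse_args(__doc__)
    cfg = make_config(args.seed, args.out)
    data, filtered = prepare(cfg, args.out, with_filter=True)
    marks = pipeline.stage_biomarkers(cfg, data, filtered, args.out)
    dys = pipeline.stage_dysbiosis(cfg, data, filtered, marks["signature"], args.out)
    res = pipeline.stage_evaluate(
        cfg, data, filtered, marks["signature"], dys["di"], args.out
    )
    s = res["summary"]
    print("AUCs for separating cases from controls:")
    for key in ("di_auc_FRI_vs_HC", "di_auc_FRI_vs_FH",
                "composition_auc_FRI_vs_HC", "composition_auc_FRI_vs_FH"):
        print(f"  {key}: {100 * s[key]:.1f}%")
    print(f"best serum-marker AUC (FRI vs FH): "
          f"{100 * s['best_serum_marker_auc_FRI_vs_FH']:.1f}%")
    print(f"full summary: {args.out}/evaluation_summary.json")
    print(json.dumps(s["di_kruskal"], indent=2))


if __name__ == "__main__":
    main()
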