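"""Biomarker discovery: Kruskal-Wallis + LDA effect-size scoring of the
filtered genera, covariate-adjusted negative-binomial GLMs for the three
group comparisons, and construction of the enriched/depleted signature."""

from _common import make_config, parse_args, prepare
from dysbiom import pipeline


def main():
    args = parse_args(__doc__)
    cfg = make_config(args.seed, args.out)
    data, filtered = prepare(cfg, args.out, with_filter=True)
    res = pipeline.stage_biomarkers(cfg, data, filtered, args.out)
    lef = res["lefse"]
    hits = lef.loc[lef["passed"]].reindex(
        lef.loc[lef["passed"], "lda_score"].abs().sort_values(ascending=False).index
    )
    print(f"{len(hits)} genera pass the LDA-score threshold "
          f"({cfg.lda_threshold}); top 5 by |score|:")
    print(hits.head(5)[["lda_score", "enriched_group"]].to_string(float_format="%.2f"))
    glm_sig = res["glm"].loc[res["glm"]["p"] < cfg.alpha]
    print(f"GLM: {glm_sig.index.nunique()} genera significant in >=1 comparison")
    sig = res["signature"]
    print(f"signature ({sig.provenance}): {len(sig.enriched_in_case)} case-enriched, "
          f"{len(sig.enriched_in_control)} control-enriched")


if __name__ == "__main__":
    main()
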