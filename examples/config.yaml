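# Analysis configuration with the workflow's standard defaults spelled out.
gq_min: 30.0        # keep records with genotype quality strictly above this
ad_min: 10          # keep records with alt-allele depth strictly above this
ffpe_mode: flag     # "flag" keeps formalin-artifact suspects annotated; "drop" removes them
share_rule: all     # group-common = intersection over members ("min_share" + min_share_k for >= k)
min_share_k: null
denominator: universe  # n1 counts common variants in pathway-annotated genes only ("all" counts every one)
alpha: 0.05         # FDR threshold for the "enriched" call
ci_method: katz     # "katz" log-ratio interval; "conditional" exact interval of the (count, total) table
ci_level: 0.95
two_sided: false    # upper-tail exact test (enrichment only)
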