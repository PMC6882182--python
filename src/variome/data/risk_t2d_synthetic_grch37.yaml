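# Likelihood-ratio polygenic risk model: Type 2 Diabetes, GRCh37.
# SYNTHETIC illustrative numbers: the per-genotype likelihood ratios and the
# pre-test probability below are placeholders demonstrating the odds-update
# method, NOT curated clinical content. Non-diagnostic: edit freely.
disease: Type 2 Diabetes (synthetic example model)
pre_test_probability: 0.25
variants:
  - {contig: "10", pos: 114758349, ref: C, alt: T, rsid: rs7903146,   # TCF7L2
     lr: {hom_ref: 0.85, het: 1.15, hom_alt: 1.60}}
  - {contig: "6", pos: 20661250, ref: C, alt: T, rsid: rs7754840,     # CDKAL1
     lr: {hom_ref: 0.93, het: 1.10, hom_alt: 1.25}}
  - {contig: "9", pos: 22134094, ref: T, alt: C, rsid: rs10811661,    # CDKN2A/B
     lr: {hom_ref: 0.90, het: 1.05, hom_alt: 1.20}}
  - {contig: "16", pos: 53820527, ref: T, alt: A, rsid: rs9939609,    # FTO
     lr: {hom_ref: 0.92, het: 1.08, hom_alt: 1.22}}
absent_hom_ref: false
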