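# Pharmacogenomic rule: Simvastatin / SLCO1B1 c.521T>C (rs4149056), GRCh37.
# Diplotype keys are joint zygosity tuples in site order.
# Illustrative, non-diagnostic content drawn from the CPIC guideline for
# SLCO1B1 and simvastatin-induced myopathy: edit freely.
drug: Simvastatin
gene: SLCO1B1
sites:
  - {contig: "12", pos: 21331549, ref: T, alt: C, rsid: rs4149056}
diplotypes:
  hom_ref:
    diplotype: "c.521 T/T"
    phenotype: "Normal function"
    recommendation: "Standard dosing per label."
    source: CPIC
  het:
    diplotype: "c.521 T/C"
    phenotype: "Intermediate function"
    recommendation: >-
      Intermediate SLCO1B1 transporter function; elevated myopathy risk at
      higher simvastatin doses. Consider a lower dose or an alternative statin.
    source: CPIC
  hom_alt:
    diplotype: "c.521 C/C"
    phenotype: "Low function"
    recommendation: >-
      Low SLCO1B1 transporter function; high myopathy risk. Consider an
      alternative statin or the lowest effective dose with CK surveillance.
    source: CPIC
absent_hom_ref: false
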