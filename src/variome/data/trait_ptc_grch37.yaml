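# Physical-trait model: PTC (phenylthiocarbamide) bitter tasting, TAS2R38.
# GRCh37 coordinates. Single-site proxy (rs713598, c.145G>C, A49P) for the
# taster (PAV) haplotype. Illustrative, non-diagnostic content: edit freely.
name: PTC bitter tasting (TAS2R38 proxy)
variants:
  - {contig: "7", pos: 141673345, ref: G, alt: C, rsid: rs713598}
phenotypes:
  hom_ref: "unlikely taster"
  het: "likely taster"
  hom_alt: "likely taster"
default: undetermined
absent_hom_ref: false
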