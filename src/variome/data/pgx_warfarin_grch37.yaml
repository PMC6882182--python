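# Pharmacogenomic rule: Warfarin / CYP2C9 *2 *3 + VKORC1 -1639G>A, GRCh37.
# Joint zygosity keys are (rs1799853, rs1057910, rs9923231) in order.
# Combinations implying >2 CYP2C9 variant alleles are omitted and report
# as 'uncallable'. Illustrative, non-diagnostic content: edit freely.
drug: Warfarin
gene: CYP2C9/VKORC1
sites:
- contig: '10'
  pos: 96702047
  ref: C
  alt: T
  rsid: rs1799853
- contig: '10'
  pos: 96741053
  ref: A
  alt: C
  rsid: rs1057910
- contig: '16'
  pos: 31107689
  ref: C
  alt: T
  rsid: rs9923231
diplotypes:
  hom_ref,hom_ref,hom_ref:
    diplotype: CYP2C9 *1/*1; VKORC1 -1639 G/G
    phenotype: CYP2C9 Normal metabolizer; VKORC1 normal sensitivity
    recommendation: Standard label-based dose selection.
    source: CPIC
  hom_ref,hom_ref,het:
    diplotype: CYP2C9 *1/*1; VKORC1 -1639 G/A
    phenotype: CYP2C9 Normal metabolizer; VKORC1 increased sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_ref,hom_ref,hom_alt:
    diplotype: CYP2C9 *1/*1; VKORC1 -1639 A/A
    phenotype: CYP2C9 Normal metabolizer; VKORC1 high sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_ref,het,hom_ref:
    diplotype: CYP2C9 *1/*3; VKORC1 -1639 G/G
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 normal sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_ref,het,het:
    diplotype: CYP2C9 *1/*3; VKORC1 -1639 G/A
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 increased sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_ref,het,hom_alt:
    diplotype: CYP2C9 *1/*3; VKORC1 -1639 A/A
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 high sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_ref,hom_alt,hom_ref:
    diplotype: CYP2C9 *3/*3; VKORC1 -1639 G/G
    phenotype: CYP2C9 Poor metabolizer; VKORC1 normal sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_ref,hom_alt,het:
    diplotype: CYP2C9 *3/*3; VKORC1 -1639 G/A
    phenotype: CYP2C9 Poor metabolizer; VKORC1 increased sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_ref,hom_alt,hom_alt:
    diplotype: CYP2C9 *3/*3; VKORC1 -1639 A/A
    phenotype: CYP2C9 Poor metabolizer; VKORC1 high sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  het,hom_ref,hom_ref:
    diplotype: CYP2C9 *1/*2; VKORC1 -1639 G/G
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 normal sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  het,hom_ref,het:
    diplotype: CYP2C9 *1/*2; VKORC1 -1639 G/A
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 increased sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  het,hom_ref,hom_alt:
    diplotype: CYP2C9 *1/*2; VKORC1 -1639 A/A
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 high sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  het,het,hom_ref:
    diplotype: CYP2C9 *2/*3; VKORC1 -1639 G/G
    phenotype: CYP2C9 Poor metabolizer; VKORC1 normal sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  het,het,het:
    diplotype: CYP2C9 *2/*3; VKORC1 -1639 G/A
    phenotype: CYP2C9 Poor metabolizer; VKORC1 increased sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  het,het,hom_alt:
    diplotype: CYP2C9 *2/*3; VKORC1 -1639 A/A
    phenotype: CYP2C9 Poor metabolizer; VKORC1 high sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_alt,hom_ref,hom_ref:
    diplotype: CYP2C9 *2/*2; VKORC1 -1639 G/G
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 normal sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_alt,hom_ref,het:
    diplotype: CYP2C9 *2/*2; VKORC1 -1639 G/A
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 increased sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
  hom_alt,hom_ref,hom_alt:
    diplotype: CYP2C9 *2/*2; VKORC1 -1639 A/A
    phenotype: CYP2C9 Intermediate metabolizer; VKORC1 high sensitivity
    recommendation: Reduced warfarin dose requirement expected; use a validated pharmacogenetic
      dosing algorithm incorporating CYP2C9 and VKORC1.
    source: CPIC
absent_hom_ref: false
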