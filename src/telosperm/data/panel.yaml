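# Default 11-SNP telomere-length panel.
#
# The rsIDs and gene labels are the canonical GWAS loci used to build
# telomere genetic scores. Effect alleles, per-allele weights (literature
# effect-size scale, kb-equivalent arbitrary units) and minor-allele
# frequencies are LITERATURE-DERIVED PLACEHOLDERS for European-ancestry
# populations: every analysis must treat this file as configuration, not
# ground truth, and any real study should substitute its own values.
snps:
  - snp_id: rs412658
    gene: ZNF676
    major_allele: T
    minor_allele: C
    effect_allele: T
    weight: 0.048
    maf: 0.36
  - snp_id: rs2736100
    gene: TERT
    major_allele: A
    minor_allele: C
    effect_allele: C
    weight: 0.078
    maf: 0.49
  - snp_id: rs3027234
    gene: CTC1
    major_allele: C
    minor_allele: T
    effect_allele: C
    weight: 0.046
    maf: 0.23
  - snp_id: rs6028466
    gene: DHX35
    major_allele: A
    minor_allele: G
    effect_allele: A
    weight: 0.054
    maf: 0.15
  - snp_id: rs6772228
    gene: PXK
    major_allele: T
    minor_allele: A
    effect_allele: T
    weight: 0.041
    maf: 0.04
  - snp_id: rs7675998
    gene: NAF1
    major_allele: G
    minor_allele: A
    effect_allele: G
    weight: 0.074
    maf: 0.22
  - snp_id: rs8105767
    gene: ZNF208
    major_allele: T
    minor_allele: G
    effect_allele: G
    weight: 0.048
    maf: 0.29
  - snp_id: rs9420907
    gene: OBFC1
    major_allele: A
    minor_allele: C
    effect_allele: C
    weight: 0.069
    maf: 0.13
  - snp_id: rs11125529
    gene: ACYP2
    major_allele: C
    minor_allele: A
    effect_allele: A
    weight: 0.056
    maf: 0.14
  - snp_id: rs10936599
    gene: TERC
    major_allele: C
    minor_allele: T
    effect_allele: C
    weight: 0.097
    maf: 0.25
  - snp_id: rs755017
    gene: ZBTB46
    major_allele: A
    minor_allele: G
    effect_allele: G
    weight: 0.062
    maf: 0.13
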