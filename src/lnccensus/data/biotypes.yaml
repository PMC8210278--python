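# Collapse of GENCODE gene_type values into the three internal biotype classes.
# Any gene_type not listed here is classed as "other".
protein_coding:
  - protein_coding
lncRNA:
  - lncRNA
  - lincRNA
  - antisense
  - processed_transcript
  - sense_intronic
  - sense_overlapping
  - 3prime_overlapping_ncRNA
  - 3prime_overlapping_ncrna
  - bidirectional_promoter_lncRNA
  - macro_lncRNA
  - non_coding
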