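# Broad-antigen serology groups, multi-allele haplotypes and generic HLA
# keywords added to the allele surface map.  The published curated membership
# tables are not public; these are editable stand-ins seeded from the
# worked examples in the literature.
broad_antigens:
  HLA-A9:
    - HLA-A*23
    - HLA-A*24
  HLA-A10:
    - HLA-A*25
    - HLA-A*26
  HLA-B14:
    - HLA-B*14:01
    - HLA-B*14:02
  HLA-DR2:
    - HLA-DRB1*15
    - HLA-DRB1*16
haplotypes:
  HLA-A1-B8-DR3:
    - HLA-A*01
    - HLA-B*08
    - HLA-DRB1*03
  HLA-A3-B7-DR15:
    - HLA-A*03
    - HLA-B*07
    - HLA-DRB1*15
generic_keywords:
  - HLA class I
  - HLA class II
  - HLA linked
  - HLA associated
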