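fixture,field,note
haycock_burden.csv,"Glioma daly ci","source prints '134.46 119.42-150.86)' with the opening parenthesis dropped; transcribed as 134.46 (119.42-150.86)"
haycock_burden.csv,"Endometrial cancer incidence ci","source prints the incidence CI inverted as (6.49-5.97); transcribed as (5.97, 6.49)"
haycock_printed.csv,"total daly per_sd_longer upper","table prints 2,163.63 while the abstract prints 2,163.83; the table value is carried"
li_printed.csv,"Lung cancer daly excess","table prints 511.36 but the running text prints 511.26; the table value is carried"
li_or.csv,"all rows ci","source prints Li odds ratios without confidence intervals; bounds left MISSING"
snp_panel.csv,"rs78148049 alleles","source prints compound alleles 'C/T C/T' and a compound frequency; stored MISSING"
snp_panel.csv,"gene_is_telomere_maintenance","flag printed once per gene block in the source; carried forward to unflagged SNPs of the block; NA stored as unknown"
snp_panel.csv,"multi-study rows","for SNPs reported by several studies the first-listed study's N, GWAS flag and population are transcribed"
ld/chr8.tsv,"rs28365964 row","source prints NA for every cell of this row; kept fully MISSING"
ld/*.tsv,"layout","lower-triangular transcription; the reader mirrors to a full symmetric matrix"
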