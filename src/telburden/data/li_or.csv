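disease_name,or_per_sd,ci_lower,ci_upper,direction,source,significant
Thyroid cancer,2.83,,,per_sd_longer,li,true
Lymphomas and multiple myeloma,1.66,,,per_sd_longer,li,true
Uterine fibroid,1.66,,,per_sd_longer,li,true
Benign prostatic hyperplasia,1.46,,,per_sd_longer,li,true
Leukemia,2.01,,,per_sd_longer,li,true
Lung cancer,1.81,,,per_sd_longer,li,true
Skin cancer (including melanoma),1.45,,,per_sd_longer,li,true
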