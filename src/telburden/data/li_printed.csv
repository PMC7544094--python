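cause_name,measure,direction,excess,excess_lower,excess_upper
Thyroid cancer,incidence,per_sd_longer,8.18,7.83,8.62
Lymphomas and multiple myeloma,incidence,per_sd_longer,10.69,10.03,11.95
Uterine fibroid,incidence,per_sd_longer,77.71,59.23,100.72
Benign prostatic hyperplasia,incidence,per_sd_longer,62.35,55.62,69.14
Leukemia,incidence,per_sd_longer,8.3,7.88,8.68
Lung cancer,incidence,per_sd_longer,26.53,25.77,27.22
Skin cancer (including melanoma),incidence,per_sd_longer,37.64,25.84,51.53
total,incidence,per_sd_longer,231.42,192.2,277.86
Thyroid cancer,daly,per_sd_longer,21.93,20.39,23.9
Lymphomas and multiple myeloma,daly,per_sd_longer,94.72,88.99,104.14
Uterine fibroid,daly,per_sd_longer,10.71,5.92,18.29
Benign prostatic hyperplasia,daly,per_sd_longer,19.61,12.74,27.9
Leukemia,daly,per_sd_longer,151.32,144.77,157.36
Lung cancer,daly,per_sd_longer,511.36,498.57,523.36
Skin cancer (including melanoma),daly,per_sd_longer,30.62,24.22,35.37
total,daly,per_sd_longer,840.28,795.6,890.32
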