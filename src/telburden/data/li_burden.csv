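cause_name,measure,value,ci_lower,ci_upper,population,year
Thyroid cancer,incidence,4.46,4.27,4.7,Europe,2017
Thyroid cancer,daly,11.97,11.12,13.04,Europe,2017
Lymphomas and multiple myeloma,incidence,16.32,15.31,18.24,Europe,2017
Lymphomas and multiple myeloma,daly,144.59,135.83,158.96,Europe,2017
Uterine fibroid,incidence,118.03,89.95,152.97,Europe,2017
Uterine fibroid,daly,16.27,9,27.78,Europe,2017
Benign prostatic hyperplasia,incidence,135.73,121.06,150.51,Europe,2017
Benign prostatic hyperplasia,daly,42.68,27.74,60.73,Europe,2017
Leukemia,incidence,8.24,7.82,8.62,Europe,2017
Leukemia,daly,150.16,143.66,156.15,Europe,2017
Lung cancer,incidence,32.57,31.62,33.41,Europe,2017
Lung cancer,daly,627.59,611.9,642.32,Europe,2017
Skin cancer (including melanoma),incidence,84.05,57.7,115.05,Europe,2017
Skin cancer (including melanoma),daly,68.37,54.09,78.98,Europe,2017
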