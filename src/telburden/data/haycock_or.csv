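disease_name,or_per_sd,ci_lower,ci_upper,direction,source,significant
Lung adenocarcinoma,3.19,2.40,4.22,per_sd_longer,haycock,true
Malignant skin melanoma,1.87,1.55,2.26,per_sd_longer,haycock,true
Endometrial cancer,1.31,1.07,1.61,per_sd_longer,haycock,true
Ovary cancer (serous LMP),4.35,2.39,7.94,per_sd_longer,haycock,true
Testicular germ-cell cancer,1.76,1.02,3.04,per_sd_longer,haycock,true
Bladder cancer,2.19,1.32,3.66,per_sd_longer,haycock,true
Glioma,5.27,3.15,8.81,per_sd_longer,haycock,true
Neuroblastoma,2.98,1.92,4.62,per_sd_longer,haycock,true
Kidney cancer,1.55,1.08,2.23,per_sd_longer,haycock,true
Coronary heart disease,1.28,1.11,1.49,per_sd_shorter,haycock,true
Aortic aneurysm,1.59,1.23,2.04,per_sd_shorter,haycock,true
Alzheimer disease and other dementias,1.19,1.02,1.41,per_sd_shorter,haycock,true
Type I diabetes mellitus,1.41,1.02,1.96,per_sd_shorter,haycock,true
Interstitial lung disease,11.11,6.67,20.00,per_sd_shorter,haycock,true
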