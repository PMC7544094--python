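cause_name,measure,value,ci_lower,ci_upper,population,year
Lung adenocarcinoma,incidence,11.56,11.22,11.86,Europe,2017
Lung adenocarcinoma,daly,222.74,217.17,227.96,Europe,2017
Malignant skin melanoma,incidence,11.60,8.27,13.33,Europe,2017
Malignant skin melanoma,daly,53.25,39.55,63.18,Europe,2017
Endometrial cancer,incidence,6.23,5.97,6.49,Europe,2017
Endometrial cancer,daly,23.82,22.62,25.02,Europe,2017
Ovary cancer (serous LMP),incidence,0.04,0.03,0.04,Europe,2017
Ovary cancer (serous LMP),daly,0.55,0.53,0.57,Europe,2017
Testicular germ-cell cancer,incidence,3.05,2.84,3.27,Europe,2017
Testicular germ-cell cancer,daly,8.84,8.20,9.58,Europe,2017
Bladder cancer,incidence,11.26,10.84,11.64,Europe,2017
Bladder cancer,daly,72.93,70.02,75.87,Europe,2017
Glioma,incidence,8.39,7.29,9.30,Europe,2017
Glioma,daly,134.46,119.42,150.86,Europe,2017
Neuroblastoma,incidence,0.012,0.010,0.013,Europe,2017
Neuroblastoma,daly,0.18,0.16,0.21,Europe,2017
Kidney cancer,incidence,9.11,8.39,9.48,Europe,2017
Kidney cancer,daly,79.79,74.51,82.74,Europe,2017
Coronary heart disease,incidence,190.81,171.96,211.00,Europe,2017
Coronary heart disease,daly,"2,106.22","2,060.06","2,167.79",Europe,2017
Aortic aneurysm,incidence,NA,NA,NA,Europe,2017
Aortic aneurysm,daly,57.09,55.47,58.72,Europe,2017
Alzheimer disease and other dementias,incidence,101.07,90.31,112.58,Europe,2017
Alzheimer disease and other dementias,daly,410.16,382.77,438.18,Europe,2017
Type I diabetes mellitus,incidence,9.59,8.70,10.59,Europe,2017
Type I diabetes mellitus,daly,62.99,55.19,71.48,Europe,2017
Interstitial lung disease,incidence,4.44,4.08,4.82,Europe,2017
Interstitial lung disease,daly,27.75,22.96,31.78,Europe,2017
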