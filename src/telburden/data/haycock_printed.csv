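cause_name,measure,direction,excess,excess_lower,excess_upper
Lung adenocarcinoma,incidence,per_sd_longer,25.31,16.18,37.22
Malignant skin melanoma,incidence,per_sd_longer,10.09,6.38,14.62
Endometrial cancer,incidence,per_sd_longer,1.93,0.44,3.80
Ovary cancer (serous LMP),incidence,per_sd_longer,0.12,0.05,0.25
Testicular germ-cell cancer,incidence,per_sd_longer,2.32,0.06,6.22
Bladder cancer,incidence,per_sd_longer,13.40,3.60,29.95
Glioma,incidence,per_sd_longer,35.83,18.04,65.54
Neuroblastoma,incidence,per_sd_longer,0.02,0.01,0.04
Kidney cancer,incidence,per_sd_longer,5.01,0.73,11.21
total,incidence,per_sd_longer,94.04,45.49,168.84
Lung adenocarcinoma,daly,per_sd_longer,487.79,311.83,717.21
Malignant skin melanoma,daly,per_sd_longer,46.33,29.29,67.10
Endometrial cancer,daly,per_sd_longer,7.38,1.67,14.53
Ovary cancer (serous LMP),daly,per_sd_longer,1.85,0.77,3.84
Testicular germ-cell cancer,daly,per_sd_longer,6.72,0.18,18.03
Bladder cancer,daly,per_sd_longer,86.79,23.34,193.99
Glioma,daly,per_sd_longer,574.14,289.09,1050.12
Neuroblastoma,daly,per_sd_longer,0.37,0.17,0.67
Kidney cancer,daly,per_sd_longer,43.88,6.38,98.14
total,daly,per_sd_longer,1255.25,662.71,2163.63
Coronary heart disease,incidence,per_sd_shorter,53.43,20.99,93.50
Alzheimer disease and other dementias,incidence,per_sd_shorter,19.20,2.02,41.44
Type I diabetes mellitus,incidence,per_sd_shorter,3.93,0.19,9.21
Interstitial lung disease,incidence,per_sd_shorter,44.93,25.20,84.44
total,incidence,per_sd_shorter,121.49,48.40,228.58
Coronary heart disease,daly,per_sd_shorter,589.74,231.68,1032.05
Aortic aneurysm,daly,per_sd_shorter,33.68,13.13,59.37
Alzheimer disease and other dementias,daly,per_sd_shorter,77.93,8.20,168.17
Type I diabetes mellitus,daly,per_sd_shorter,25.83,1.26,60.47
Interstitial lung disease,daly,per_sd_shorter,280.57,157.35,527.28
total,daly,per_sd_shorter,1007.75,411.63,1847.34
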