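narrow_name,broad_name,narrow_count,broad_count,fraction,source
Idiopathic pulmonary fibrosis,Interstitial lung disease,,,0.268,Danish National Registry of Patients
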