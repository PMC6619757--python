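# Small-molecule constants (Da).  v1
# name	monoisotopic	average
water	18.010565	18.01528
ammonia	17.026549	17.03052
hydrogen	1.0078250319	1.00794
proton	1.00727646688	1.00727646688
formic_acid	46.005480	46.0254
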