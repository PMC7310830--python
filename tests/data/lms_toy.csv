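sex,age_months,L,M,S
male,192,-1.45,19.78,0.130
male,216,-1.45,20.34,0.130
female,192,-1.20,20.04,0.125
female,216,-1.20,20.52,0.125
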