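temperature_c,alpha_mmol_per_l_per_mmhg
10,0.058
15,0.050
20,0.043
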