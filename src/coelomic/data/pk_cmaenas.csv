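temperature_c,pk1
10,6.057
15,6.029
20,6.000
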