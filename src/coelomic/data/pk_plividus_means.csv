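pco2_level,temperature_c,pk1
ambient,10,6.445
ambient,15,6.256
ambient,20,6.158
elevated,10,6.466
elevated,15,6.281
elevated,20,6.069
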