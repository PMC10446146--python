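label,ti_mass_ng,censored,loq_ng,volume_m3,duration_h
Test 2A,,true,1.0,303.7,96
Test 2B,,true,1.0,229.6,72
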