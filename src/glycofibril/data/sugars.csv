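name,molar_mass,electrons,tpsa
ribose,150.13,80,90.2
glucose,180.16,96,110.0
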