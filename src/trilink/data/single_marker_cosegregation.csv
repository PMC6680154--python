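marker,pin_plants,thrum_plants,total,recombinants
PvSLP1,92,99,191,0
PvSLL1,74,100,174,0
PvSLL2,56,90,146,2
PvGlo,64,93,157,0
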