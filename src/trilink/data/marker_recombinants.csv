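# Single-crossover recombinants from the Oakleaf-S-Hose in Hose crosses that
# were genotyped by gel blot.  interval: flank1_to_S = Oakleaf-to-S,
# S_to_flank2 = S-to-Hose in Hose.  Plants p1-p12 are the individually
# described blots; rows r13-r29 are synthetic stand-ins for the remaining
# blotted recombinants, which were reported only in aggregate (no marker
# assortment observed), with morphs assigned arbitrarily but consistently.
individual_id,crossover_interval,morph
p1,S_to_flank2,pin
p2,flank1_to_S,thrum
p3,flank1_to_S,thrum
p4,S_to_flank2,thrum
p5,flank1_to_S,thrum
p6,S_to_flank2,pin
p7,S_to_flank2,pin
p8,flank1_to_S,thrum
p9,flank1_to_S,thrum
p10,flank1_to_S,thrum
p11,flank1_to_S,thrum
p12,flank1_to_S,thrum
r13,flank1_to_S,thrum
r14,flank1_to_S,thrum
r15,flank1_to_S,thrum
r16,flank1_to_S,thrum
r17,flank1_to_S,thrum
r18,flank1_to_S,thrum
r19,flank1_to_S,thrum
r20,flank1_to_S,thrum
r21,flank1_to_S,thrum
r22,flank1_to_S,thrum
r23,S_to_flank2,pin
r24,S_to_flank2,pin
r25,S_to_flank2,pin
r26,S_to_flank2,pin
r27,S_to_flank2,thrum
r28,S_to_flank2,thrum
r29,S_to_flank2,thrum
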