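# RFLP calls for PvSLL1 (pin 3.0 kb / thrum 2.8 kb, thrum allele in coupling
# with S) and PvSLL2 (pin <15 kb / thrum 5.0 kb, thrum allele in coupling
# with S) on the blotted recombinants.  p6 shows a novel 2.5-kb PvSLL1 band
# (mutation or recombination, unresolved); p9 lacks the PvSLL2 thrum allele.
# Calls for the synthetic r-rows follow the aggregate report of no marker
# assortment.
individual_id,marker_id,allele_state,bands
p1,PvSLL1,pin_only_homozygous,3.0/3.0
p2,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p3,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p4,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p5,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p6,PvSLL1,novel_band,3.0/2.5
p7,PvSLL1,pin_only_homozygous,3.0/3.0
p8,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p9,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p10,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p11,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p12,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r13,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r14,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r15,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r16,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r17,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r18,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r19,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r20,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r21,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r22,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r23,PvSLL1,pin_only_homozygous,3.0/3.0
r24,PvSLL1,pin_only_homozygous,3.0/3.0
r25,PvSLL1,pin_only_homozygous,3.0/3.0
r26,PvSLL1,pin_only_homozygous,3.0/3.0
r27,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r28,PvSLL1,thrum_pin_heterozygous,3.0/2.8
r29,PvSLL1,thrum_pin_heterozygous,3.0/2.8
p1,PvSLL2,pin_only_homozygous,<15/<15
p2,PvSLL2,thrum_pin_heterozygous,<15/5.0
p3,PvSLL2,thrum_pin_heterozygous,<15/5.0
p4,PvSLL2,thrum_pin_heterozygous,<15/5.0
p5,PvSLL2,thrum_pin_heterozygous,<15/5.0
p6,PvSLL2,pin_only_homozygous,<15/<15
p7,PvSLL2,pin_only_homozygous,<15/<15
p8,PvSLL2,thrum_pin_heterozygous,<15/5.0
p9,PvSLL2,pin_only_homozygous,<15/<15
p10,PvSLL2,thrum_pin_heterozygous,<15/5.0
p11,PvSLL2,thrum_pin_heterozygous,<15/5.0
p12,PvSLL2,thrum_pin_heterozygous,<15/5.0
r13,PvSLL2,thrum_pin_heterozygous,<15/5.0
r14,PvSLL2,thrum_pin_heterozygous,<15/5.0
r15,PvSLL2,thrum_pin_heterozygous,<15/5.0
r16,PvSLL2,thrum_pin_heterozygous,<15/5.0
r17,PvSLL2,thrum_pin_heterozygous,<15/5.0
r18,PvSLL2,thrum_pin_heterozygous,<15/5.0
r19,PvSLL2,thrum_pin_heterozygous,<15/5.0
r20,PvSLL2,thrum_pin_heterozygous,<15/5.0
r21,PvSLL2,thrum_pin_heterozygous,<15/5.0
r22,PvSLL2,thrum_pin_heterozygous,<15/5.0
r23,PvSLL2,pin_only_homozygous,<15/<15
r24,PvSLL2,pin_only_homozygous,<15/<15
r25,PvSLL2,pin_only_homozygous,<15/<15
r26,PvSLL2,pin_only_homozygous,<15/<15
r27,PvSLL2,thrum_pin_heterozygous,<15/5.0
r28,PvSLL2,thrum_pin_heterozygous,<15/5.0
r29,PvSLL2,thrum_pin_heterozygous,<15/5.0
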