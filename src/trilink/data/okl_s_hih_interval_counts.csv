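# Per-cross recombinant counts of the six Oakleaf-S-Hose in Hose crosses.
# total counts all scored progeny of the cross including the exceptional
# (short homostyle) individual of cross 5: the published per-cross cell
# lists the 116 canonical-class progeny, while the published pooled totals
# (784, 2075) include the homostyle, so total is recorded here as 117.
cross_id,female_parent,male_parent,informative_parent,total,rec_interval_1,rec_interval_2,intra_s
cross_1,pin-1,thrum-1,thrum-1,413,3,2,0
cross_2,pin-2,thrum-1,thrum-1,430,2,0,0
cross_3,thrum-1,pin-3,thrum-1,448,3,3,0
cross_4,pin-4,thrum-2,thrum-2,500,6,5,0
cross_5,pin-5,thrum-2,thrum-2,117,3,6,1
cross_6,thrum-2,pin-4,thrum-2,167,11,1,0
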