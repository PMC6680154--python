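cross_id,female_parent,male_parent,informative_parent,total,rec_interval_1,rec_interval_2,intra_s
cross_1,pin-1,thrum-1,thrum-1,146,1,0,0
cross_2,pin-1,thrum-2,thrum-2,61,0,1,0
cross_3,pin-1,thrum-3,thrum-3,299,5,2,0
cross_4,pin-1,thrum-4,thrum-4,95,1,0,0
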