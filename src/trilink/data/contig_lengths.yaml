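# Physical lengths (kb) of the assembled sequence groups flanking the
# S locus, and the anchored-contig / distance-range inputs for kb-per-cM
# scaling.
sequence_groups_kb:
  group_A_contig_S_left: 119
  group_B_contig_S_right: 888
  group_C_pool1_unanchored: 325
  group_D_pool2_unanchored: 178
pvglo_anchored_contig_kb: 888
s_to_hih_range_cm: [0.39, 1.53]
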