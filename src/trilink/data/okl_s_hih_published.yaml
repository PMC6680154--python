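# Published pooled rows of the Oakleaf-S-Hose in Hose three-point table,
# used to reconcile fitted values against the printed ones.  Note the
# thrum-1 S-HIH cell: the printed pooled count (6) disagrees with the sum
# of the per-cross counts (2+0+3 = 5); the printed distance 0.39 cM equals
# 5/1291, while 6/1291 would be 0.46 cM.
pools:
  thrum-1:
    total: 1291
    interval_1: {count: 8, distance_cm: 0.62}
    interval_2: {count: 6, distance_cm: 0.39}
    intra_s: {count: 0, distance_cm: 0.00}
  thrum-2:
    total: 784
    interval_1: {count: 20, distance_cm: 2.55}
    interval_2: {count: 12, distance_cm: 1.53}
    intra_s: {count: 1, distance_cm: 0.13}
combined:
  total: 2075
  interval_1: {count: 28, range_cm: [0.62, 2.55]}
  interval_2: {count: 17, range_cm: [0.39, 1.53]}
  intra_s: {count: 1, distance_cm: 0.05}
published_coincidence:
  # Printed per-pool coefficients of coincidence; the per-pool double-
  # crossover counts behind them are not restated in the tabulated data,
  # so these values are recorded for reference, not recomputed.
  thrum-1: {c: 103.8, interference: -102.8}
  thrum-2: {c: 8.6, interference: -7.6}
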