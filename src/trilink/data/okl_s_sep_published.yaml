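# Published rows of the Oakleaf-S-sepaloid three-point table.
pools:
  thrum-1:
    total: 146
    interval_1: {count: 1, distance_cm: 0.68}
    interval_2: {count: 0}
  thrum-2:
    total: 61
    interval_1: {count: 0}
    interval_2: {count: 1, distance_cm: 1.64}
  thrum-3:
    total: 299
    interval_1: {count: 5, distance_cm: 1.67}
    interval_2: {count: 2, distance_cm: 0.67}
  thrum-4:
    total: 95
    interval_1: {count: 1, distance_cm: 1.05}
    interval_2: {count: 0}
combined:
  total: 601
  interval_1: {count: 7, range_cm: [0.68, 1.67]}
  interval_2: {count: 3, range_cm: [0.67, 1.64]}
published_coincidence:
  thrum-3: {c: 50.1, interference: -49.1}
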