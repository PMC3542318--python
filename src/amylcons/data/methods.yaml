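# Method registry: thresholds, windows, minimum sequence lengths, and
# checksums of the packaged numeric tables.  Boundary semantics are literal:
# gt/lt are strict, ge/le inclusive.
methods:
  aggrescan:
    kind: native
    min_length: 5
    scale: aggrescan_a3v
    hotspot_threshold: -0.02
    comparator: gt
    # window length by sequence length: [max_length, window]; null = no cap
    window_rule: [[75, 5], [175, 7], [300, 9], [null, 11]]
  amylmut:
    kind: adapter
    min_length: 20
    rule: [[score, ge, 1.0]]
  apd:
    kind: native
    min_length: 5
    window: 5
    scale: packing_density
    threshold: 21.4
    comparator: gt
  bsc:
    kind: native
    min_length: 4
    scale: beta_propensity
    min_window: 4
    max_window: 20
    window_threshold: 1.2
    y_threshold: 20.0
    top_k: 400
  hce:
    kind: adapter
    min_length: 6
    rule: [[energy, lt, -27.0]]
  netcssp:
    kind: adapter
    min_length: 7
    rule: [[hbp, gt, 1.0], [pbeta, gt, 6.0]]
    derived:
      hbp: [ratio, pbeta, phelix]
  pafig:
    kind: adapter
    min_length: 6
    rule: [[ri, ge, 7.0]]
  pattern:
    kind: native
    min_length: 6
    pattern: hexapeptide
  secstr:
    kind: adapter
    min_length: 1
    rule: [[switch, ge, 1.0]]
  tango:
    kind: adapter
    min_length: 1
    rule: [[beta, gt, 5.0]]
  waltz:
    kind: native
    min_length: 6
    pssm: hexapeptide_ph7
    threshold: 79.0
    comparator: ge

scales:
  aggrescan_a3v:
    file: aggrescan_a3v.tsv
    source: "Conchillo-Sole et al., BMC Bioinformatics 8:65 (2007)"
    sha256: f0e12e08a248cd4629ab2f710b6ed170b809afd71ae706c7a776a7cbfd98a393
  beta_propensity:
    file: beta_propensity.tsv
    source: "Chou & Fasman, Biochemistry 13:222-245 (1974)"
    sha256: 66d0eda94b6f131501b09601a78d19b2ff2b6dcc0c7acd8bad32e18d6fecc706
  packing_density:
    file: packing_density.tsv
    source: "after Galzitskaya et al., PLoS Comput Biol 2:e177 (2006); see file header"
    sha256: 51272702584230a6f4a89dd72a9e466700232361145cfe35f40eef1dbc905e1f

pssms:
  hexapeptide_ph7:
    file: hexapeptide_pssm.tsv
    width: 6
    sha256: 2c6fba0af3ec1e7d8ecd749a15f4b5b8a7375790164cd91b113eac18f330999d

patterns:
  hexapeptide:
    file: hexapeptide_pattern.txt
    sha256: df23a07708849e9b94a01b0897f2690ef8ab815634af598ac7a9d7874314998b
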