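# Pairing schemes for the A·A lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: AA_N6_N1_w
    annotation: WC-side
    bonds:
      - "W:N6 > C:N1"
  - id: AA_N6_N1_c
    annotation: WC-side
    bonds:
      - "C:N6 > W:N1"
  - id: AA_major
    annotation: major-groove
    bonds:
      - "W:N6 > C:N7"
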