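# Pairing schemes for the A·G lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: AG_anti
    annotation: WC-side
    bonds:
      - "W:N6 > C:O6"
      - "C:N1 > W:N1"
  - id: AG_major
    annotation: major-groove
    bonds:
      - "W:N6 > C:O6"
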