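# Pairing schemes for the G·G lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: GG_N1_O6_w
    annotation: WC-side
    bonds:
      - "W:N1 > C:O6"
      - "C:N2 > W:N7"
  - id: GG_N1_O6_c
    annotation: WC-side
    bonds:
      - "C:N1 > W:O6"
      - "W:N2 > C:N7"
  - id: GG_minor
    annotation: minor-groove
    bonds:
      - "W:N2 > C:N3"
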