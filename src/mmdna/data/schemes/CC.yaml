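# Pairing schemes for the C·C lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: CC_N4_N3_w
    annotation: WC-side
    bonds:
      - "W:N4 > C:N3"
  - id: CC_N4_N3_c
    annotation: WC-side
    bonds:
      - "C:N4 > W:N3"
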