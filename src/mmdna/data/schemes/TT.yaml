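# Pairing schemes for the T·T lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: TT_wobble_w
    annotation: WC-side
    bonds:
      - "W:N3 > C:O2"
      - "C:N3 > W:O4"
  - id: TT_wobble_c
    annotation: WC-side
    bonds:
      - "C:N3 > W:O2"
      - "W:N3 > C:O4"
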