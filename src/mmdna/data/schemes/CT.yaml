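# Pairing schemes for the C·T lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: CT_pair_w
    annotation: WC-side
    bonds:
      - "W:N4 > C:O2"
      - "C:N3 > W:N3"
  - id: CT_single
    annotation: WC-side
    bonds:
      - "W:N4 > C:O4"
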