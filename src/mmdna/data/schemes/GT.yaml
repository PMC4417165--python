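# Pairing schemes for the G·T lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: GT_wobble
    annotation: WC-side
    bonds:
      - "W:N1 > C:O2"
      - "C:N3 > W:O6"
  - id: GT_sugar
    annotation: minor-groove
    bonds:
      - "W:N2 > C:O4'"
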