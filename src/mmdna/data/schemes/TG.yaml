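# Pairing schemes for the T·G lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: TG_wobble
    annotation: WC-side
    bonds:
      - "C:N1 > W:O2"
      - "W:N3 > C:O6"
  - id: TG_sugar
    annotation: minor-groove
    bonds:
      - "C:N2 > W:O4'"
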