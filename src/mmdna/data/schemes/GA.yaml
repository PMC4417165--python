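# Pairing schemes for the G·A lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: GA_anti
    annotation: WC-side
    bonds:
      - "C:N6 > W:O6"
      - "W:N1 > C:N1"
  - id: GA_major
    annotation: major-groove
    bonds:
      - "C:N6 > W:O6"
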