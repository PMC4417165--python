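# Pairing schemes for the T·A lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: TA_WC
    annotation: WC-side
    bonds:
      - "C:N6 > W:O4"
      - "W:N3 > C:N1"
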