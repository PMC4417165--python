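# Pairing schemes for the A·T lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: AT_WC
    annotation: WC-side
    bonds:
      - "W:N6 > C:O4"
      - "C:N3 > W:N1"
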