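# Pairing schemes for the C·A lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: CA_wobble
    annotation: WC-side
    bonds:
      - "C:N6 > W:N3"
      - "W:N4 > C:N1"
  - id: CA_reverse
    annotation: WC-side
    bonds:
      - "W:N4 > C:N7"
      - "C:N6 > W:N3"
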