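# Pairing schemes for the C·G lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: CG_WC
    annotation: WC-side
    bonds:
      - "W:N4 > C:O6"
      - "C:N1 > W:N3"
      - "C:N2 > W:O2"
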