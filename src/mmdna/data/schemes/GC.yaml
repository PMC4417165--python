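# Pairing schemes for the G·C lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: GC_WC
    annotation: WC-side
    bonds:
      - "C:N4 > W:O6"
      - "W:N1 > C:N3"
      - "W:N2 > C:O2"
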