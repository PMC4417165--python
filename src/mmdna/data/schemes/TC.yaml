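# Pairing schemes for the T·C lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: TC_pair_c
    annotation: WC-side
    bonds:
      - "C:N4 > W:O2"
      - "W:N3 > C:N3"
  - id: TC_single
    annotation: WC-side
    bonds:
      - "C:N4 > W:O4"
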