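# Pairing schemes for the A·C lesion pair
# (editable seed topologies; donor > acceptor atom pairs across
#  the Watson (W) and Crick (C) lesion bases).
schemes:
  - id: AC_wobble
    annotation: WC-side
    bonds:
      - "W:N6 > C:N3"
      - "C:N4 > W:N1"
  - id: AC_reverse
    annotation: WC-side
    bonds:
      - "C:N4 > W:N7"
      - "W:N6 > C:N3"
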