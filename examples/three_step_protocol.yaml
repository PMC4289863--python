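# Three-stage fitting protocol for a three-component assembly whose parts
# are annotated L1, hormone and alphaCT (as produced by the synthetic
# benchmark; adapt names for other structures).  Each map is scoped to the
# component it describes.  Usable with:
#   ectofit fit start.pdb --protocol three_step_protocol.yaml \
#       --maps L1=map_L1.mrc,hormone=map_hormone.mrc,alphaCT=map_alphaCT.mrc
stages:
  - label: fit-L1-alphaCT
    mobile: [L1, alphaCT]
    restrained: [hormone]
    maps:
      - {map: L1, selection: L1}
      - {map: alphaCT, selection: alphaCT}
    max_steps: 2000
  - label: fit-hormone
    mobile: [hormone]
    restrained: [alphaCT]
    maps:
      - {map: hormone, selection: hormone}
    max_steps: 2000
  - label: fit-all
    mobile: [L1, hormone, alphaCT]
    maps:
      - {map: L1, selection: L1}
      - {map: hormone, selection: hormone}
      - {map: alphaCT, selection: alphaCT}
    max_steps: 2000
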