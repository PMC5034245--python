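# Functional-state grouping of rhodopsin structures.  Group membership is
# configuration, not computation: fill in the (PDB id, chain) pairs of the
# entries you analyse.  The three-group scheme:
#   1  ground-state rhodopsin + early intermediates (batho, lumi)
#   2  elongated cytoplasmic ends of TM5/TM6
#   3  opsin / metarhodopsin-II with the outward-tilted TM6; the in-crystallo
#      photoactivated 2I37 chains belong here by their TM7 anchor conformation
groups:
  - id: 1
    description: "ground state + batho/lumi intermediates"
    members: []          # e.g. [[1U19, A], [1U19, B]]
  - id: 2
    description: "elongated TM5/TM6 cytoplasmic ends"
    members: []
  - id: 3
    description: "opsin/meta-II, tilted TM6 (includes 2I37 chains)"
    members: []          # e.g. [[3CAP, A], [2I37, A]]
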