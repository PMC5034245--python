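# Transmembrane segment definitions for bovine rhodopsin (author numbering,
# inclusive ranges; chain '*' means "first chain" — override per structure).
#
# Only the two middle segments are fixed by published residue ranges:
# TM5m 207-215 (pi conformation) and TM7m 294-301 (3/10 conformation,
# retinal anchor Lys296).  A figure caption elsewhere gives 208-215 and
# 293-300 for the same segments; the ranges below follow the body text —
# edit here if you prefer the caption ranges.  All other boundaries are
# editable placeholders: replace them with your preferred TM definitions
# before running a survey.
segments:
  - {name: TM1e, chain: "*", start: 35,  end: 46}    # placeholder, edit
  - {name: TM1c, chain: "*", start: 47,  end: 60}    # placeholder, edit
  - {name: TM2c, chain: "*", start: 71,  end: 85}    # placeholder, edit
  - {name: TM2e, chain: "*", start: 86,  end: 98}    # placeholder, edit
  - {name: TM3e, chain: "*", start: 107, end: 122}   # placeholder, edit
  - {name: TM3c, chain: "*", start: 123, end: 139}   # placeholder, edit
  - {name: TM4c, chain: "*", start: 150, end: 160}   # placeholder, edit
  - {name: TM4e, chain: "*", start: 161, end: 172}   # placeholder, edit
  - {name: TM5e, chain: "*", start: 200, end: 206}   # placeholder, edit
  - {name: TM5m, chain: "*", start: 207, end: 215}   # fixed: pi segment
  - {name: TM5c, chain: "*", start: 216, end: 225}   # placeholder, edit
  - {name: TM6c, chain: "*", start: 244, end: 264}   # placeholder, edit
  - {name: TM6e, chain: "*", start: 265, end: 276}   # placeholder, edit
  - {name: TM7e, chain: "*", start: 286, end: 293}   # placeholder, edit
  - {name: TM7m, chain: "*", start: 294, end: 301}   # fixed: 3/10 anchor segment
  - {name: TM7c, chain: "*", start: 302, end: 308}   # placeholder, edit
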