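# Pinned monoisotopic mass constants (Da). Values are fixed here rather than
# pulled from a library at run time so that every computed m/z is bit-stable
# across installations. Sources: CODATA 2018 (electron), AME2020 (nuclides).
elements:
  H1: 1.00782503207
  C12: 12.0
  C13: 13.00335483507
  N14: 14.0030740048
  O16: 15.99491461956
  Na23: 22.9897692809
  S32: 31.97207100
  electron: 0.00054857990907

# Tag definitions. Additions are given as elemental compositions of the NET
# mass change per acylation (esterification of one O-H: + C3H4O for the light
# propanoyl tag, + 13C3 H4 O for the heavy tag). Masses are computed from the
# element table at load time.
tags:
  propanoyl:
    light_composition: {C12: 3, H1: 4, O16: 1}
    heavy_composition: {C13: 3, H1: 4, O16: 1}
    max_tags_per_compound: 4

# Positive-mode adducts as compositions applied to the neutral (or, for
# "none", intrinsic-cation) mass. electron: -1 encodes the electron lost on
# cation formation; at ppm accuracy it is not negligible (~0.5 mDa).
adducts:
  "H+": {H1: 1, electron: -1}
  "Na+": {Na23: 1, electron: -1}
  "NH4+": {N14: 1, H1: 4, electron: -1}
  "none": {}
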