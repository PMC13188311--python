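# Curated torsion-pattern library.
#
# Each pattern is a SMARTS query with four mapped atoms; atoms :2 and :3
# are the rotatable-bond atoms, :1 and :4 fix the chemical context.
# `boundaries` are bin edges in degrees, strictly increasing within
# (-180, 180].  Bins are half-open (lower, upper] and wrap across +-180:
# with k edges b_1 < ... < b_k, bin 1 is (b_k - 360, b_1] and bin i is
# (b_{i-1}, b_i].  The number of edges is the pattern multiplicity.
# Priority = position in this file (earlier = more specific); the final
# pattern is a catch-all and must never be removed.
#
# Bin edges are placed at the barriers between the well-known rotamer
# wells of each bond class (e.g. the three staggered wells of an
# sp3-sp3 bond, the cis/trans wells of an amide).  User libraries in the
# same format can be supplied to replace this default.
patterns:
  - id: aromatic_aromatic
    smarts: "[a:1]:[a:2]-!@[a:3]:[a:4]"
    boundaries: [-90.0, 0.0, 90.0, 180.0]
  - id: amide
    smarts: "[!#1:1][NX3:2]-!@[CX3:3]=[OX1:4]"
    boundaries: [-90.0, 90.0]
  - id: conjugated
    smarts: "[!#1:1][CX3,c:2]-!@[CX3,c:3][!#1:4]"
    boundaries: [-90.0, 90.0]
  - id: sp3_sp2
    smarts: "[!#1:1][CX4:2]-!@[CX3,c:3][!#1:4]"
    boundaries: [-60.0, 60.0, 180.0]
  - id: sp3_sp3
    smarts: "[!#1:1][CX4:2]-!@[CX4:3][!#1:4]"
    boundaries: [-120.0, 0.0, 120.0]
  - id: generic
    smarts: "[!#1:1]~[*:2]-!@[*:3]~[!#1:4]"
    boundaries: [-120.0, 0.0, 120.0]
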