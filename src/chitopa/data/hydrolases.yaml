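# Default subsite rule sets for the hydrolase presets ("strongly
# favours"/"almost absolute specificity" collapsed to absolute
# requirements; a weighted mode exists for softer specificity).
#
# Convention: the scissile bond sits between subsites {-1} and {+1};
# bond index = residue index of the {-1} residue.  "constraints" gives
# the allowed residue(s) per subsite; "occupancy" lists subsites that
# must hold a residue of the current fragment (residue-constrained
# subsites are implicitly occupancy-required).
chitinosanase:
  # DA/XX rule: D at {-2}, A at {-1}, no downstream constraint.
  constraints:
    -2: D
    -1: A
  occupancy: [-2, -1, 1]
  mode: absolute

ChiB:
  constraints:
    -1: A
  occupancy: [-2, -1, 1]
  mode: absolute

ChT:
  # human chitotriosidase: subsite preferences resembling ChiB
  constraints:
    -1: A
  occupancy: [-2, -1, 1]
  mode: absolute

Csn174:
  constraints:
    -1: D
    1: D
  occupancy: [-2, -1, 1, 2]
  mode: absolute

lysozyme:
  # long cleft: needs one more occupied subsite on the non-reducing side,
  # which bounds its smallest products (no cuts closer than 2 residues to
  # the non-reducing end of a fragment).
  constraints:
    -2: A
    -1: A
    1: A
  occupancy: [-3, -2, -1, 1, 2]
  mode: absolute
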