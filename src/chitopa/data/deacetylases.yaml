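# Default subsite-preference weights for the (de)acetylase presets.
#
# These numeric weights are editable model defaults: the underlying
# enzymology is qualitative ("prefers", "slight preference"), so only the
# orderings between presets are meaningful.  Convention: subsite {0}
# holds the D being acetylated; negative subsites lie towards the
# non-reducing end, positive towards the reducing end.  "prefer" ~ 10:1,
# "mild" ~ 2-3:1, "slight" ~ 2:1.
uniform:
  mode: acetylation
  end_weight: 1.0
  weights:
    -2: {A: 1.0, D: 1.0}
    -1: {A: 1.0, D: 1.0}
    1: {A: 1.0, D: 1.0}

AnCDA:
  mode: acetylation
  end_weight: 1.0
  weights:
    -2: {A: 3.0, D: 1.0}
    -1: {A: 10.0, D: 1.0}
    1: {A: 2.0, D: 1.0}

PesCDA:
  mode: acetylation
  end_weight: 1.0
  weights:
    -2: {A: 2.0, D: 1.0}
    -1: {A: 12.0, D: 1.0}
    1: {A: 3.0, D: 1.0}

CnCDA4:
  mode: acetylation
  end_weight: 1.0
  weights:
    -1: {A: 1.0, D: 10.0}

PgtCDA:
  mode: acetylation
  end_weight: 1.0
  weights:
    -1: {A: 1.0, D: 2.0}
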