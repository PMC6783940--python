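# Lineage-score weight matrix: score name -> panel name -> weight.
# Each row sums to zero, so a sample with equal values on all five
# panels scores zero on every lineage axis.
weights:
  Pluripotency:
    Pluripotent: 1.5
    Ectoderm: -0.25
    Mesendoderm: -0.25
    Mesoderm: -0.5
    Endoderm: -0.5
  Ectoderm:
    Pluripotent: -0.25
    Ectoderm: 1.75
    Mesendoderm: -0.5
    Mesoderm: -0.5
    Endoderm: -0.5
  Mesendoderm:
    Pluripotent: -1.0
    Ectoderm: -0.5
    Mesendoderm: 1.0
    Mesoderm: 0.25
    Endoderm: 0.25
  Endoderm:
    Pluripotent: -1.0
    Ectoderm: -1.0
    Mesendoderm: 0.5
    Mesoderm: -0.5
    Endoderm: 2.0
  Mesoderm:
    Pluripotent: -1.0
    Ectoderm: -1.0
    Mesendoderm: 0.5
    Mesoderm: 2.0
    Endoderm: -0.5
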