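# Marker-gene panels for pluripotency and the three germ-layer routes.
panels:
  Pluripotent:
    - OCT4
    - NANOG
  Ectoderm:
    - FGF5
    - PAX6
    - P75
  Mesendoderm:
    - MIXL1
    - T
  Mesoderm:
    - NKX2.5
    - MESP1
  Endoderm:
    - SOX17
    - PDX1
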