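noise_sd: 0.25
pcr_replicates: 3
seed: 0
reference_offset: 18.0
coding_scheme: nominal
surfaces:
- gene: OCT4
  baseline_ct: 24.0
  coefficients:
    intercept: -1.0
    FGF2: 0.5
    CHIR: -3.5
    CHIR^2: -0.5
    FGF2:CHIR: -0.75
- gene: NANOG
  baseline_ct: 24.5
  coefficients:
    intercept: -1.0
    FGF2: 0.5
    CHIR: -3.5
    CHIR^2: -0.5
    FGF2:CHIR: -0.75
- gene: FGF5
  baseline_ct: 25.0
  coefficients:
    intercept: 0.0
    FGF2: -0.7
    TGFb^2: -0.6
    CHIR: -3.5
    CHIR^2: -0.5
    FGF2:CHIR: 0.7
- gene: PAX6
  baseline_ct: 25.5
  coefficients:
    intercept: 0.0
    FGF2: -0.7
    TGFb^2: -0.6
    CHIR: -3.5
    CHIR^2: -0.5
    FGF2:CHIR: 0.7
- gene: P75
  baseline_ct: 26.0
  coefficients:
    intercept: 0.0
    FGF2: -0.7
    TGFb^2: -0.6
    CHIR: -3.5
    CHIR^2: -0.5
    FGF2:CHIR: 0.7
- gene: MIXL1
  baseline_ct: 26.5
  coefficients:
    intercept: 2.0
    CHIR: 2.0
    CHIR^2: -1.0
- gene: T
  baseline_ct: 27.0
  coefficients:
    intercept: 2.0
    CHIR: 2.0
    CHIR^2: -1.0
- gene: NKX2.5
  baseline_ct: 27.5
  coefficients:
    intercept: 1.5
    CHIR: -2.27
    CHIR^2: -3.4
    FGF2:CHIR: 0.6
- gene: MESP1
  baseline_ct: 28.0
  coefficients:
    intercept: 1.5
    CHIR: -2.27
    CHIR^2: -3.4
    FGF2:CHIR: 0.6
- gene: SOX17
  baseline_ct: 28.5
  coefficients:
    intercept: 1.5
    FGF2: 0.6
    CHIR: 2.5
    CHIR^2: 0.8
- gene: PDX1
  baseline_ct: 29.0
  coefficients:
    intercept: 1.5
    FGF2: 0.6
    CHIR: 2.5
    CHIR^2: 0.8
controls:
  mTeSR1:
    OCT4: 0.0
    NANOG: 0.0
    FGF5: 0.0
    PAX6: 0.0
    P75: 0.0
    MIXL1: 0.0
    T: 0.0
    NKX2.5: 0.0
    MESP1: 0.0
    SOX17: 0.0
    PDX1: 0.0
  E8:
    OCT4: 0.3
    NANOG: 0.3
    FGF5: -1.0
    PAX6: -1.0
    P75: -1.0
    MIXL1: -1.0
    T: -1.0
    NKX2.5: -1.0
    MESP1: -1.0
    SOX17: -1.0
    PDX1: -1.0
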