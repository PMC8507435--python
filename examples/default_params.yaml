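diatom:
  trophic_class: diatom
  UmRT: 0.81
  Q10: 2.0
  Tref: 20.0
  mrtRT: 0.07
  mortality_order: linear
  BRfrac: 0.05
  redco: 1.71
  AR: 0.5
  SDA: 0.0
  NCmin: 0.07
  NCopt: 0.15
  NCmax: 0.2
  NO3Copt: 0.14
  NO3Cmax: 0.19
  PCminNCmin: 0.1
  PCminNCmax: 0.16
  PCmin: 0.005
  PCopt: 0.02
  PCmax: 0.04
  SCmin: 0.1
  SCopt: 0.25
  SCmax: 0.35
  KtN: 0.014
  KtP: 0.0031
  KtSi: 0.028
  ChlCmax: 0.06
  alphaChl: 0.9
  relPS: 2.0
  PSDOC: 0.06
  ESD: 24.0
  Ccell: 3.88646106754675e-10
  optCR: 0.0
  PR: {}
  relPhag: 1.0
  AEo: 0.25
  AEm: 0.75
  sed: 0.5069661308411216
green:
  trophic_class: green
  UmRT: 0.81
  Q10: 2.0
  Tref: 20.0
  mrtRT: 0.07
  mortality_order: linear
  BRfrac: 0.05
  redco: 1.71
  AR: 0.5
  SDA: 0.0
  NCmin: 0.07
  NCopt: 0.15
  NCmax: 0.2
  NO3Copt: 0.14
  NO3Cmax: 0.19
  PCminNCmin: 0.1
  PCminNCmax: 0.16
  PCmin: 0.005
  PCopt: 0.02
  PCmax: 0.04
  KtN: 0.014
  KtP: 0.0031
  ChlCmax: 0.035
  alphaChl: 0.5
  relPS: 2.0
  PSDOC: 0.06
  ESD: 6.0
  Ccell: 1.830819501663728e-11
  optCR: 0.0
  PR: {}
  relPhag: 1.0
  AEo: 0.25
  AEm: 0.75
  sed: 0.0
protozoo:
  trophic_class: protozoo
  UmRT: 0.81
  Q10: 2.0
  Tref: 20.0
  mrtRT: 0.007
  mortality_order: quadratic
  BRfrac: 0.05
  redco: 0.0
  AR: 0.5
  SDA: 0.3
  NCmin: 0.07
  NCopt: 0.16
  NCmax: 0.22
  PCmin: 0.006
  PCopt: 0.022
  PCmax: 0.045
  relPS: 1.0
  PSDOC: 0.06
  ESD: 30.0
  Ccell: 1.7046845774696713e-09
  optCR: 0.5
  PR:
    diatom: 0.75
    green: 1.0
    CM: 1.0
  relPhag: 1.0
  AEo: 0.25
  AEm: 0.75
  sed: 0.0
CM:
  trophic_class: CM
  UmRT: 0.81
  Q10: 2.0
  Tref: 20.0
  mrtRT: 0.07
  mortality_order: linear
  BRfrac: 0.05
  redco: 1.71
  AR: 0.5
  SDA: 0.3
  NCmin: 0.07
  NCopt: 0.15
  NCmax: 0.2
  NO3Copt: 0.14
  NO3Cmax: 0.19
  PCminNCmin: 0.1
  PCminNCmax: 0.16
  PCmin: 0.002
  PCopt: 0.008
  PCmax: 0.02
  KtN: 0.005
  KtP: 0.001
  ChlCmax: 0.025
  alphaChl: 0.35
  relPS: 2.0
  PSDOC: 0.06
  ESD: 12.0
  Ccell: 1.2901702628559965e-10
  optCR: 0.4
  PR:
    green: 1.0
  relPhag: 0.05
  AEo: 0.25
  AEm: 0.75
  sed: 0.0
NCM:
  trophic_class: NCM
  UmRT: 0.81
  Q10: 2.0
  Tref: 20.0
  mrtRT: 0.07
  mortality_order: linear
  BRfrac: 0.05
  redco: 0.0
  AR: 0.5
  SDA: 0.3
  NCmin: 0.07
  NCopt: 0.16
  NCmax: 0.22
  PCmin: 0.006
  PCopt: 0.022
  PCmax: 0.045
  ChlCmax: 0.02
  alphaChl: 0.3
  relPS: 1.0
  PSDOC: 0.06
  lossChl_rate: 0.15
  ESD: 60.0
  Ccell: 1.2012835494716988e-08
  optCR: 0.2
  PR:
    diatom: 1.0
    green: 0.5
    CM: 1.0
    protozoo: 0.5
  relPhag: 0.5
  AEo: 0.25
  AEm: 0.75
  sed: 0.0
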