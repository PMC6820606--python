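# Default population-PK configuration for atezolizumab (IV infusion).
#
# The typical disposition parameters are fixed by the published summary
# pharmacokinetics: clearance 0.2 L/day, steady-state volume 6.9 L and a
# terminal half-life of ~27 days.  Those three constraints under-determine
# the four two-compartment parameters; the V1/V2 split and Q below honour
# all three simultaneously and match the magnitudes of the published
# phase-1 model.  Covariate exponents, fold-changes, omega and sigma were
# never published at full precision: the values below are calibration
# constants chosen so that simulated reference-population exposure spans
# are realistic for an IgG1 antibody; substitute published estimates here
# if you have them.
name: atezolizumab-default
typical:
  CL: 0.200      # L/day
  V1: 3.28       # L
  Q: 0.546       # L/day
  V2: 3.62       # L
covariates:
  reference: {weight: 77.0, albumin: 40.0, tumor_size: 63.0, sex: M, ada: negative}
  effects:
    - {parameter: CL, covariate: weight, form: power, reference: 77.0, exponent: 0.75}
    - {parameter: CL, covariate: albumin, form: power, reference: 40.0, exponent: -1.10}
    - {parameter: CL, covariate: tumor_size, form: power, reference: 63.0, exponent: 0.13}
    - {parameter: CL, covariate: sex, form: fold, level: F, fold: 0.87}
    - {parameter: CL, covariate: ada, form: fold, level: positive, fold: 1.16}
    - {parameter: V1, covariate: weight, form: power, reference: 77.0, exponent: 0.55}
    - {parameter: V1, covariate: sex, form: fold, level: F, fold: 0.90}
    - {parameter: Q, covariate: weight, form: power, reference: 77.0, exponent: 0.75}
    - {parameter: V2, covariate: weight, form: power, reference: 77.0, exponent: 0.55}
omega:
  # lower triangle, log-scale, parameter order CL, V1, Q, V2
  - [0.070]
  - [0.030, 0.055]
  - [0.000, 0.000, 0.020]
  - [0.000, 0.000, 0.000, 0.020]
sigma:
  prop: 0.20     # proportional residual (fraction)
  add: 1.0       # additive residual (ug/mL)
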