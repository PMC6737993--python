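# Default model coefficient sets (after Janssen): the original crop
# coefficients and recovery fractions, with the default-form indigenous
# supply equations as refit per agro-ecological zone.  Units as in
# coefficients_parameterized.yaml.
version: 1
source: janssen_default
zones:
  NGS:
    crop:
      a: {N: 30.0, P: 200.0, K: 30.0}
      d: {N: 70.0, P: 600.0, K: 120.0}
      r: {N: 5.0, P: 0.4, K: 2.0}
      y_max: 10000.0
    recovery: {N: 0.50, P: 0.10, K: 0.50}
    supply:
      N:
        family: linear
        intercept: 22.80
        terms:
          - {predictor: OC_tot, coef: 2.54}
        r2: 0.11
      P:
        family: linear
        intercept: 5.46
        terms:
          - {predictor: OC_tot, coef: -0.22}
          - {predictor: P_av, coef: 0.72}
        r2: 0.57
      K:
        family: linear
        intercept: 37.53
        terms:
          - {predictor: OC_tot, coef: -1.60}
          - {predictor: K_exch, coef: 248.05}
        r2: 0.46
  SS:
    crop:
      a: {N: 30.0, P: 200.0, K: 30.0}
      d: {N: 70.0, P: 600.0, K: 120.0}
      r: {N: 5.0, P: 0.4, K: 2.0}
      y_max: 10000.0
    recovery: {N: 0.50, P: 0.10, K: 0.50}
    supply:
      N:
        family: linear
        intercept: 24.87
        terms:
          - {predictor: OC_tot, coef: 0.61}
        r2: 0.03
      P:
        family: linear
        intercept: 3.29
        terms:
          - {predictor: OC_tot, coef: -0.11}
          - {predictor: P_av, coef: 0.31}
        r2: 0.56
      K:
        family: linear
        intercept: 39.13
        terms:
          - {predictor: OC_tot, coef: -2.50}
          - {predictor: K_exch, coef: 237.21}
        r2: 0.36
  All:
    crop:
      a: {N: 30.0, P: 200.0, K: 30.0}
      d: {N: 70.0, P: 600.0, K: 120.0}
      r: {N: 5.0, P: 0.4, K: 2.0}
      y_max: 10000.0
    recovery: {N: 0.50, P: 0.10, K: 0.50}
    supply:
      N:
        family: linear
        intercept: 22.06
        terms:
          - {predictor: OC_tot, coef: 2.36}
        r2: 0.10
      P:
        family: linear
        intercept: 4.74
        terms:
          - {predictor: OC_tot, coef: 0.01}
          - {predictor: P_av, coef: 0.42}
        r2: 0.35
      K:
        family: linear
        intercept: 36.23
        terms:
          - {predictor: OC_tot, coef: -1.53}
          - {predictor: K_exch, coef: 248.42}
        r2: 0.43
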