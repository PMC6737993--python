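# Savanna-calibrated coefficient sets for maize, one block per
# agro-ecological zone (NGS: Northern Guinea Savanna, SS: Sudan Savanna,
# All: pooled).  Crop coefficients: physiological efficiency at maximum
# accumulation (a) and dilution (d), kg grain per kg nutrient; minimum
# uptake r, kg/ha; potential yield y_max, kg/ha.  Recovery: average
# fertilizer recovery fractions.  Supply: indigenous-supply equations on
# topsoil properties (OC_tot, N_tot g/kg; P_av mg/kg; K_exch cmol_c/kg;
# pH in water 1:1), value in kg/ha.
version: 1
source: parameterized
zones:
  NGS:
    crop:
      a: {N: 35.0, P: 200.0, K: 25.0}
      d: {N: 79.0, P: 527.0, K: 117.0}
      r: {N: 4.0, P: 0.5, K: 4.5}
      y_max: 10000.0
    recovery: {N: 0.42, P: 0.16, K: 0.54}
    supply:
      N:
        family: linear
        intercept: -20.54
        terms:
          - {predictor: OC_tot, coef: 0.60}
          - {predictor: N_tot, coef: 130.92}
        r2: 0.57
      P:
        family: linear
        intercept: -12.16
        terms:
          - {predictor: pH, coef: 2.71}
          - {predictor: P_av, coef: 0.71}
        r2: 0.61
      K:
        family: linear
        intercept: 27.10
        terms:
          - {predictor: K_exch, coef: 246.22}
        r2: 0.55
  SS:
    crop:
      a: {N: 32.0, P: 164.0, K: 24.0}
      d: {N: 79.0, P: 528.0, K: 136.0}
      r: {N: 6.1, P: 0.8, K: 7.3}
      y_max: 10000.0
    recovery: {N: 0.32, P: 0.08, K: 0.37}
    supply:
      N:
        family: polynomial
        intercept: 11.64
        terms:
          - {predictor: N_tot, coef: 155.41, power: 3}
        r2: 0.52
      P:
        family: polynomial
        intercept: -4.11
        terms:
          - {predictor: pH, coef: 1.40}
          - {predictor: P_av, coef: 0.0005, power: 3}
        r2: 0.66
      K:
        family: linear
        intercept: 228.73
        terms:
          - {predictor: pH, coef: -35.30}
          - {predictor: K_exch, coef: 275.30}
        r2: 0.60
  All:
    crop:
      a: {N: 35.0, P: 199.0, K: 24.0}
      d: {N: 79.0, P: 528.0, K: 124.0}
      r: {N: 4.0, P: 0.5, K: 4.5}
      y_max: 10000.0
    recovery: {N: 0.40, P: 0.15, K: 0.52}
    supply:
      N:
        family: polynomial
        intercept: 9.56
        terms:
          - {predictor: N_tot, coef: 147.28, power: 2}
        r2: 0.56
      P:
        family: linear
        intercept: -8.35
        terms:
          - {predictor: pH, coef: 2.20}
          - {predictor: P_av, coef: 0.43}
        r2: 0.50
      K:
        family: linear
        intercept: 26.35
        terms:
          - {predictor: K_exch, coef: 247.97}
        r2: 0.52
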