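# Built-in process library for the two-protein Rab5/Rab7 conversion model.
#
# Each regulatory slot (gef5, gap5, gef7, gap7) lists its mutually exclusive
# kinetic alternatives.  A gef7 alternative couples a mandatory cross-activation
# component (driven by active Rab5) with an optional auto-activation component
# (driven by active Rab7); every other slot contributes a single component.
# The Cartesian product of the four slots spans 3 * 3 * 7 * 2 = 126 structures.
#
# Forms: intrinsic  rate = k                     (constant, uncatalysed)
#        michaelis_menten  rate = V*X/(Km+X)     (saturating catalysis)
#        sigmoidal  rate = V*X^h/(Km^h+X^h)      (Hill response, h fixed)
#        exchange_inhibition  rate = V*Km/(Km+X) (decreasing in the inhibitor)
#        linear     rate = k*X
#
# Bounds may be overridden at load time; defaults follow the study ranges:
# kinetic rates and half-saturation constants in [1e-3, 4] (1/s, conc. units).

defaults:
  rate_bounds: [1.0e-3, 4.0]
  km_bounds: [1.0e-3, 4.0]
  hill_exponent: 3.0

root:
  flux_bounds: [1.0e-3, 4.0]      # K1, k1, K2, k2 (GDI association/dissociation)
  init_bounds: [0.0, 2.0]         # r5_0, R5_0, r7_0, R7_0
  scale_bounds: [1.0e3, 1.0e5]    # K, intensity per concentration unit
  onset_bounds: [5.0, 195.0]      # td, offset between model onset and first sample (s)

slots:
  gef5:
    - {name: mm_auto, form: michaelis_menten, regulator: R5}
    - {name: sigmoidal_auto, form: sigmoidal, regulator: R5}
    - {name: exchange_inhibition, form: exchange_inhibition, regulator: R7}
  gap5:
    - {name: intrinsic, form: intrinsic, regulator: none}
    - {name: mm_by_R7, form: michaelis_menten, regulator: R7}
    - {name: sigmoidal_by_R7, form: sigmoidal, regulator: R7}
  gef7:
    - name: mm_cross
      cross: {form: michaelis_menten, regulator: R5}
    - name: mm_cross+mm_auto
      cross: {form: michaelis_menten, regulator: R5}
      auto: {form: michaelis_menten, regulator: R7}
    - name: mm_cross+sigmoidal_auto
      cross: {form: michaelis_menten, regulator: R5}
      auto: {form: sigmoidal, regulator: R7}
    - name: sigmoidal_cross
      cross: {form: sigmoidal, regulator: R5}
    - name: sigmoidal_cross+mm_auto
      cross: {form: sigmoidal, regulator: R5}
      auto: {form: michaelis_menten, regulator: R7}
    - name: sigmoidal_cross+sigmoidal_auto
      cross: {form: sigmoidal, regulator: R5}
      auto: {form: sigmoidal, regulator: R7}
    - name: linear_cross
      cross: {form: linear, regulator: R5}
  gap7:
    - {name: intrinsic, form: intrinsic, regulator: none}
    - {name: mm_by_R5, form: michaelis_menten, regulator: R5}
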