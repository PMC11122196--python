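# Example pipeline configuration.
#
# Dose coefficients for I-131 blood dosimetry, transcribed from the standard
# pre-therapeutic blood/bone-marrow dosimetry protocol for differentiated
# thyroid cancer:
#   Dk_beta  : Gy·mL·GBq⁻¹·h⁻¹  (blood self-irradiation, beta component)
#   Dk_gamma : Gy·kg^(2/3)·GBq⁻¹·h⁻¹  (whole-body-to-blood photon component)
#   l_phys   : h⁻¹  (physical decay constant, ln 2 / 8.02 d)
dose_coefficients:
  Dk_beta: 108.0
  Dk_gamma: 0.0188
  l_phys: 0.00360

fitting:
  min_points: 8
  se_factor: 2.0
  chi2_tol: 1.0e-9

grouping:
  k1_low: 0.6   # h^-1, below -> slow-repair group
  k1_high: 1.1  # h^-1, above -> fast-repair group
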