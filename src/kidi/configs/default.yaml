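# Default parameter set and reference batch scenario.
# Keys mirror KineticParams / StoichiometryParams field names verbatim;
# units: rates 1/h, K_plus_* mg/L, K_minus_* g/L, Y_shared_* g/OD,
# Y_self_* / Y_partner_* mg/OD.
parameters:
  mu_max_1: 2.961e-1
  mu_max_2: 1.658e-1
  K_plus_1: 3.300e-3
  K_plus_2: 3.881e-4
  K_minus_1: 3.091e-4
  K_minus_2: 3.923e-4
  kd_1: 1.206e-4
  kd_2: 4.024e-7
  Y_shared_1: 1.372
  Y_shared_2: 1.773
  Y_self_1: 1.550
  Y_self_2: 2.994
  Y_partner_1: 1.365
  Y_partner_2: 2.961
scenario:
  label: fig3A
  x1: 0.02
  x2: 0.02
  s_minus: 2.0
  s1_plus: 1.0
  s2_plus: 1.0
  horizon: 30.0
  feed:
    events: []
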