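# M9 minimal medium (Sambrook-style), BiGG exchange ids, uniform uptake 10.
name: M9
carbon_source: EX_glc__D_e
components:
  EX_glc__D_e: 10
  EX_nh4_e: 10
  EX_pi_e: 10
  EX_so4_e: 10
  EX_k_e: 10
  EX_na1_e: 10
  EX_cl_e: 10
  EX_mg2_e: 10
  EX_ca2_e: 10
  EX_fe2_e: 10
  EX_fe3_e: 10
  EX_ni2_e: 10
  EX_h_e: 10
  EX_h2o_e: 10
notes: Generic minimal salts medium with glucose.
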