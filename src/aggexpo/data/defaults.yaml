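# Default parameter set for the preservative aggregate-exposure pipeline.
#
# Sources of the numbers are noted inline:
#   measured   — reported physiological / regulatory constants
#   assumption — conventional defaults not fixed by the study, overridable
ingredients:
  MP:
    f_ue: 0.174            # urinary excretion fraction after oral dosing
    half_life_h: 8.0       # urinary elimination half-life (upper bound for parabens)
    dermal_absorption:
      default: 0.037       # regulatory review value for parabens, all dermal products
    conc_scenarios:
      max: 0.004           # EU regulatory maximum mass fraction (0.4%)
      typical: 0.001       # literature-typical 0.1%
  EP:
    f_ue: 0.137
    half_life_h: 8.0
    dermal_absorption:
      default: 0.037
    conc_scenarios:
      max: 0.004
      typical: 0.001
  PP:
    f_ue: 0.097
    half_life_h: 8.0
    dermal_absorption:
      default: 0.037
    conc_scenarios:
      max: 0.0019          # 0.19%
      typical: 0.001
  TCS:
    f_ue: 0.54
    half_life_h: 11.0
    dermal_absorption:     # triclosan absorption is product-specific
      default: 0.077
      deodorant: 0.077
      shower_gel: 0.072
      toothpaste: 0.113
    conc_scenarios:
      max: 0.003           # 0.3%
      typical: 0.001

products:
  toothpaste:
    route: oral_incidental
    ingested_fraction: 0.05      # retained/swallowed share of product used
    oral_absorption: 1.0
    retention_factor: 1.0        # unused on the oral route
  shampoo:
    route: dermal
    retention_factor: 0.01       # assumption: rinse-off convention
  shower_gel:
    route: dermal
    retention_factor: 0.01       # assumption: rinse-off convention
  deodorant:
    route: dermal
    retention_factor: 1.0        # assumption: leave-on convention
  shaving_cream:
    route: dermal
    retention_factor: 0.01       # assumption: rinse-off convention
  day_cream:
    route: dermal
    retention_factor: 1.0        # assumption: leave-on convention
  body_lotion:
    route: dermal
    retention_factor: 1.0        # assumption: leave-on convention

# ConsExpo parameterises toothpaste by a fixed ingested mass instead of a
# fraction of the amount used.
consexpo_fixed_ingested_g: 0.08

# Default aggregate preservative scenario: one person assumed exposed to the
# preservative in a full basket of 17 personal care products.  Amounts and
# retention factors follow regulatory-guidance conventions; the exact table
# behind the study's aggregate-scenario predictions is not public, so this
# basket is a configurable assumption, not a transcription.
aggregate_scenario:
  products:
    - {name: shower_gel,      amount_g_d: 18.67, retention_factor: 0.01}
    - {name: hand_wash_soap,  amount_g_d: 20.00, retention_factor: 0.01}
    - {name: shampoo,         amount_g_d: 10.46, retention_factor: 0.01}
    - {name: hair_conditioner, amount_g_d: 3.92, retention_factor: 0.01}
    - {name: hair_styling,    amount_g_d: 4.00,  retention_factor: 0.1}
    - {name: body_lotion,     amount_g_d: 7.82,  retention_factor: 1.0}
    - {name: face_cream,      amount_g_d: 1.54,  retention_factor: 1.0}
    - {name: hand_cream,      amount_g_d: 2.16,  retention_factor: 1.0}
    - {name: liquid_foundation, amount_g_d: 0.51, retention_factor: 1.0}
    - {name: makeup_remover,  amount_g_d: 5.00,  retention_factor: 0.1}
    - {name: eye_shadow,      amount_g_d: 0.02,  retention_factor: 1.0}
    - {name: mascara,         amount_g_d: 0.025, retention_factor: 1.0}
    - {name: eyeliner,        amount_g_d: 0.005, retention_factor: 1.0}
    - {name: lipstick,        amount_g_d: 0.057, retention_factor: 1.0}
    - {name: deodorant,       amount_g_d: 1.50,  retention_factor: 1.0}
    - {name: toothpaste,      amount_g_d: 2.75,  retention_factor: 0.05}
    - {name: mouthwash,       amount_g_d: 21.62, retention_factor: 0.1}

study_defaults:
  n_use_days: 4
  n_observation_days: 6
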