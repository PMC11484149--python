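# Base-case inputs for the abrocitinib-vs-standard-of-care cost-effectiveness
# model (Japan; JPY; percent-type inputs given in percent).
#
# The waning horizons follow the methods text (abrocitinib wanes over 10
# years to 62.0%, standard of care over 5 years to 3.0%); the input table's
# duration labels are treated as transposed.
settings:
  discount_rate_annual_pct: 2.0
  cycle_length_years: 0.5
  start_age: 38.0
  max_age: 110.0
  retirement_age: 65.0
  wtp_threshold: 5000000.0
  perspective: societal
  yen_per_usd: 131.498
  days_per_year: 365.25

clinical:
  abrocitinib:
    response_16w_pct: 42.9
    disc_16_52w_pct: 6.9
    sustained_52w_pct: 80.6
    annual_disc_post52w_pct: 6.3
    waning_horizon_years: 10.0
    longterm_response_pct: 62.0
  soc:
    response_16w_pct: 10.7
    disc_16_52w_pct: 0.0
    sustained_52w_pct: 72.5
    annual_disc_post52w_pct: 0.0
    waning_horizon_years: 5.0
    longterm_response_pct: 3.0

utilities:
  abrocitinib:
    responder: 0.88
    non_responder: 0.78
  soc:
    responder: 0.86
    non_responder: 0.61

costs:
  drug_unit_cost: 4287.40          # JPY per 100 mg pill
  doses_per_day: 1.0
  hcru_unit_costs:
    hospitalization: 695973.3
    primary_care_visit: 7096.8
  hcru_annual_freq:
    responder:
      hospitalization: 0.14
      primary_care_visit: 7.26
    non_responder:
      hospitalization: 0.20
      primary_care_visit: 11.27
  monitoring_tests:
    - {name: renal function test,      unit_cost: 110.0,  count_year1: 3, count_year2plus: 1}
    - {name: complete blood count,     unit_cost: 210.0,  count_year1: 3, count_year2plus: 1}
    - {name: liver function test,      unit_cost: 170.0,  count_year1: 3, count_year2plus: 1}
    - {name: tuberculosis testing,     unit_cost: 6100.0, count_year1: 1, count_year2plus: 0}
    - {name: hepatitis B and C testing, unit_cost: 3600.0, count_year1: 1, count_year2plus: 0}
    - {name: chest x-ray,              unit_cost: 2100.0, count_year1: 1, count_year2plus: 0}
  ae_items:
    - {name: acne,                             cost_per_event: 4776.0, annual_rate_pct: {abrocitinib: 9.3,  soc: 0.0}}
    - {name: conjunctivitis,                   cost_per_event: 1178.0, annual_rate_pct: {abrocitinib: 2.7,  soc: 7.3}}
    - {name: dermatitis atopic,                cost_per_event: 1114.0, annual_rate_pct: {abrocitinib: 9.3,  soc: 11.9}}
    - {name: headache,                         cost_per_event: 730.0,  annual_rate_pct: {abrocitinib: 13.1, soc: 14.2}}
    - {name: nasopharyngitis,                  cost_per_event: 730.0,  annual_rate_pct: {abrocitinib: 27.1, soc: 20.7}}
    - {name: nausea,                           cost_per_event: 730.0,  annual_rate_pct: {abrocitinib: 13.1, soc: 4.9}}
    - {name: oral herpes,                      cost_per_event: 1173.0, annual_rate_pct: {abrocitinib: 5.4,  soc: 2.5}}
    - {name: upper respiratory tract infection, cost_per_event: 730.0, annual_rate_pct: {abrocitinib: 15.5, soc: 14.2}}
    - {name: urinary tract infection,          cost_per_event: 841.0,  annual_rate_pct: {abrocitinib: 5.4,  soc: 4.9}}
    - {name: folliculitis,                     cost_per_event: 859.0,  annual_rate_pct: {abrocitinib: 5.4,  soc: 9.6}}
    - {name: herpes zoster,                    cost_per_event: 2591.0, annual_rate_pct: {abrocitinib: 5.4,  soc: 0.0}}
  subsequent_monthly_cost: 14451.0

productivity:
  employment_rate_pct: 83.30
  hours_per_week: 36.80
  hourly_wage: 2353.0
  baseline_pct_hours_lost: 33.6
  responder_effect_lsm: 23.4
  weeks_per_year: 52.0
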