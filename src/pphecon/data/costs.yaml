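# Default unit costs, 2012 US$.
#
# Drug prices are from the MSH International Drug Price Indicator Guide;
# consumables, transport and inpatient-stay costs from the WHO Mother-Baby
# Package costing spreadsheet (1999 prices inflated to 2012 US$). Low values
# are point x 0.5 and high values point x 2 for the WHO-sourced items; drug
# low/high are the MSH guide's lowest/highest listed supplier prices.
unit_costs:
  oxytocin_10iu:          {point: 0.2184, low: 0.0368, high: 0.7289}
  misoprostol_200ug:      {point: 0.09,   low: 0.0564, high: 0.1786}
  iv_fluids:              {point: 1.79,   low: 0.895,  high: 3.58}
  infusion_set:           {point: 0.32,   low: 0.16,   high: 0.64}
  blood_unit:             {point: 41.67,  low: 20.835, high: 83.34}
  blood_giving_set:       {point: 0.48,   low: 0.24,   high: 0.96}
  transport_per_km:       {point: 0.41,   low: 0.205,  high: 0.82}
  overnight_health_centre: {point: 1.39,  low: 0.695,  high: 2.78}
  overnight_hospital:     {point: 3.47,   low: 1.735,  high: 6.94}
  syringe:                {point: 0.07,   low: 0.035,  high: 0.14}
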