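# One-way sensitivity plan: each entry substitutes exactly one parameter of
# the base case.
plan:
  - {target: rr_bound, value: low, label: Lower bound of RR}
  - {target: rr_bound, value: high, label: Higher bound of RR}
  - {target: drug_cost_bound, value: low, label: Lower cost of drugs}
  - {target: drug_cost_bound, value: high, label: Higher cost of drugs}
  - {target: treatment_cost_multiplier, value: 0.5, label: 50% treatment cost}
  - {target: treatment_cost_multiplier, value: 2.0, label: 200% treatment cost}
  - target: stay_costs_override
    value: {overnight_health_centre: 20.0, overnight_hospital: 50.0}
    label: Health centre $20; hospital $50/night
  - {target: baseline_source, value: hundley2013, label: Home-birth evidence}
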