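# Default clinical-management recipe for one case of PPH, following the WHO
# Mother-Baby Package conventions:
#   - every treated case receives the treatment bundle (10 iU oxytocin +
#     syringe + IV fluids + infusion-giving set);
#   - hospital-origin cases: 50 % stay 7 nights in hospital;
#   - community cases present at a health post, which treats and refers 100 %
#     (half to a health centre, half directly to hospital) with one emergency
#     transport leg; health centres keep half (50 % stay 2 nights) and refer
#     the other half onward to hospital with a second transport leg;
#   - each transfusion consumes one unit of blood plus a blood giving set;
#   - each case needing additional uterotonics consumes oxytocin + syringe.
# Transport distance and blood units per transfusion are not printed in the
# source tables and are explicit configuration here.
recipe:
  bundle_oxytocin: true
  bundle_syringe: true
  bundle_iv_fluids: true
  bundle_infusion_set: true
  hospital_stay_fraction: 0.5
  hospital_stay_nights: 7
  health_centre_stay_fraction: 0.5
  health_centre_stay_nights: 2
  health_post_referral_fraction: 1.0
  health_post_to_health_centre_split: 0.5
  health_centre_onward_fraction: 0.5
  transport_km: 10.0
  blood_units_per_transfusion: 1
  severe_pph_extra_cost: 0.0
doses:
  misoprostol_tablets_per_dose: 3
  oxytocin_units_label: "10 iU"
  include_syringe_in_prophylaxis: false
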