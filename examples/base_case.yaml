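# The shipped base case: oxytocin in hospital + misoprostol in the community,
# compared with oxytocin in hospital + no community prophylaxis.
scenario:
  intervention: {hospital: oxytocin, community: misoprostol}
  comparator: {hospital: oxytocin, community: none}
  cohort_size: 1000
  mix: {hospital_fraction: 0.4, community_fraction: 0.6}
  evidence_source: tuncalp2012
  rr_bound: point
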