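# Default epidemiological inputs for the PPH prophylaxis model.
#
# Two evidence sources are shipped:
#   tuncalp2012  - mixed hospital/community trial populations (Cochrane review
#                  of prostaglandins for PPH prevention). Placebo baselines come
#                  from the misoprostol 600 ug vs placebo comparison; oxytocin
#                  baselines from the misoprostol 600 ug vs injectable
#                  uterotonics comparison.
#   hundley2013  - home-birth setting review; placebo baselines and misoprostol
#                  vs placebo relative risks only (no oxytocin arm, so this
#                  source supports community-only substitutions).
#
# Rates are proportions in [0, 1]. For baseline rates, low/high are the lowest
# and highest single-trial estimates; for relative risks they are 95 % CI
# limits. Absent bounds (not calculated in the source) are omitted.
sources:
  tuncalp2012:
    baseline_rates:
      placebo:
        pph:                    {point: 0.160, low: 0.120, high: 0.273}
        severe_pph:             {point: 0.030, low: 0.007, high: 0.097}
        additional_uterotonics: {point: 0.072, low: 0.007, high: 0.387}
        blood_transfusion:      {point: 0.008, low: 0.005, high: 0.009}
        shivering:              {point: 0.108, low: 0.000, high: 0.173}
        fever:                  {point: 0.016, low: 0.000, high: 0.043}
      oxytocin:
        pph:                    {point: 0.124, low: 0.004, high: 0.173}
        severe_pph:             {point: 0.027, low: 0.000, high: 0.065}
        additional_uterotonics: {point: 0.111, low: 0.044, high: 0.140}
        blood_transfusion:      {point: 0.011, low: 0.000, high: 0.016}
        shivering:              {point: 0.060, low: 0.000, high: 0.404}
        fever:                  {point: 0.010, low: 0.000, high: 0.070}
    relative_risks:
      misoprostol_vs_oxytocin:
        pph:                    {point: 1.43, low: 1.34, high: 1.52}
        severe_pph:             {point: 1.36, low: 1.17, high: 1.58}
        additional_uterotonics: {point: 1.35, low: 1.10, high: 1.66}
        blood_transfusion:      {point: 0.77, low: 0.59, high: 1.02}
        shivering:              {point: 2.94, low: 2.35, high: 3.67}
        fever:                  {point: 6.77, low: 5.55, high: 8.27}
      misoprostol_vs_placebo:
        pph:                    {point: 0.77, low: 0.60, high: 0.99}
        severe_pph:             {point: 0.91, low: 0.51, high: 1.63}
        additional_uterotonics: {point: 0.86, low: 0.66, high: 1.13}
        blood_transfusion:      {point: 0.24, low: 0.06, high: 0.94}
        shivering:              {point: 3.01, low: 2.68, high: 3.39}
        fever:                  {point: 5.39, low: 3.78, high: 7.69}
  hundley2013:
    baseline_rates:
      placebo:
        pph:                    {point: 0.122}
        severe_pph:             {point: 0.012}
        additional_uterotonics: {point: 0.054}
        blood_transfusion:      {point: 0.029}
        shivering:              {point: 0.178}
        fever:                  {point: 0.138}
    relative_risks:
      misoprostol_vs_placebo:
        pph:                    {point: 0.58, low: 0.38, high: 0.87}
        severe_pph:             {point: 0.20, low: 0.04, high: 0.91}
        additional_uterotonics: {point: 0.34, low: 0.16, high: 0.73}
        blood_transfusion:      {point: 0.16, low: 0.07, high: 0.38}
        shivering:              {point: 2.18, low: 1.00, high: 4.72}
        fever:                  {point: 1.40, low: 0.16, high: 12.09}
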