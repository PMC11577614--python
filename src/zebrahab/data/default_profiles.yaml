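groups:
- name: control
  n_baseline: 136
  gains_by_timepoint:
    pre:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    5min:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    1h:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    2h:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    24h:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    48h:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
  attrition:
    pre: 0.0
    5min: 0.0
    1h: 0.0
    2h: 0.014705882352941176
    24h: 0.014925373134328358
    48h: 0.030303030303030304
  p_supra: 0.85
  p_sub: 0.2
  non_responder_fraction: 0.05
  non_responder_p_supra: 0.2
  gain_cv: 0.1
  sigma_mm: 3.0
  scale_mm: 30.0
  spontaneous_mean_mm: 110.0
  spontaneous_sd_mm: 25.0
- name: low_impact
  n_baseline: 70
  gains_by_timepoint:
    pre:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    5min:
      h1: 1.0
      h2: 0.25
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    1h:
      h1: 1.0
      h2: 0.25
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    2h:
      h1: 1.0
      h2: 0.25
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    24h:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    48h:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
  attrition:
    pre: 0.0
    5min: 0.0
    1h: 0.0
    2h: 0.05714285714285714
    24h: 0.030303030303030304
    48h: 0.078125
  p_supra: 0.85
  p_sub: 0.2
  non_responder_fraction: 0.05
  non_responder_p_supra: 0.2
  gain_cv: 0.1
  sigma_mm: 3.0
  scale_mm: 30.0
  spontaneous_mean_mm: 110.0
  spontaneous_sd_mm: 25.0
- name: high_impact
  n_baseline: 69
  gains_by_timepoint:
    pre:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.0
      f2: 0.0
      f3: 1.0
    5min:
      h1: 1.0
      h2: 0.25
      h3: 0.2
      f1: 0.5
      f2: 0.8
      f3: 0.4
    1h:
      h1: 1.0
      h2: 0.25
      h3: 0.2
      f1: 0.5
      f2: 0.8
      f3: 0.4
    2h:
      h1: 1.0
      h2: 0.25
      h3: 0.2
      f1: 0.5
      f2: 0.8
      f3: 0.4
    24h:
      h1: 1.0
      h2: 0.25
      h3: 0.2
      f1: 0.5
      f2: 0.8
      f3: 0.4
    48h:
      h1: 1.0
      h2: 0.7692307692307692
      h3: 0.2
      f1: 0.3
      f2: 0.8
      f3: 0.6
  attrition:
    pre: 0.0
    5min: 0.11594202898550725
    1h: 0.01639344262295082
    2h: 0.0
    24h: 0.23333333333333334
    48h: 0.15217391304347827
  p_supra: 0.85
  p_sub: 0.2
  non_responder_fraction: 0.05
  non_responder_p_supra: 0.2
  gain_cv: 0.1
  sigma_mm: 3.0
  scale_mm: 30.0
  spontaneous_mean_mm: 110.0
  spontaneous_sd_mm: 25.0
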