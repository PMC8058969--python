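name: tas102-bevacizumab-mcrc
description: >
  TAS-102 plus bevacizumab combination therapy versus TAS-102 monotherapy in
  chemorefractory metastatic colorectal cancer, Japanese health-care payer
  perspective, 2019 costs.  Parameter triplets are the published tables
  verbatim (min = 0.75 x base, max = 1.25 x base).  Counting/discount
  conventions and per-cycle item multiplicities are the configuration
  recovered by the calibration sweep against the published base-case totals;
  the source analysis does not document them.
model:
  cycle_length_weeks: 8.0
  n_cycles: 30
  annual_discount: 0.035
  wtp_threshold: 117746.0
  counting_convention: half_cycle
  discount_convention: annualized
  reference_arm: monotherapy
  comparator_arm: combination
  psa_seed: 20210420
metadata:
  currency: USD
  exchange_rate_jpy_per_usd: 110.05
  body_weight_kg: 65.0
  body_surface_area_m2: 1.72
  wtp_threshold_note: >
    Threshold is threefold 2018 per-capita GDP of Japan; the source prints
    both $117,746 and $117,912 -- the former is configured here.
arms:
  monotherapy:
    transitions:
      progression: {base: 0.55459395, min: 0.41594546, max: 0.69324243, dist: beta_like}
      death: {base: 0.26230083, min: 0.19672562, max: 0.32787604, dist: beta_like}
      complication: {base: 0.1126958, min: 0.08452185, max: 0.14086975, dist: beta_like}
    utilities:
      stable: {base: 0.73, min: 0.5475, max: 0.9125, dist: beta_like}
      complication: {base: 0.73, min: 0.5475, max: 0.9125, dist: beta_like}
      progression: {base: 0.59, min: 0.4425, max: 0.7375, dist: beta_like}
      progression_complication: {base: 0.59, min: 0.4425, max: 0.7375, dist: beta_like}
      death: {base: 0.0, min: 0.0, max: 0.0, dist: beta_like}
    costs:
      exchange_rate_jpy_per_usd: 110.05
      body_weight_kg: 65.0
      body_surface_area_m2: 1.72
      complication_item: Costs for management of complication (monotherapy)
      items:
        - {label: TAS-102, base: 1833.66516, min: 1375.24887, max: 2292.08145, dist: gamma_like}
        - {label: Administration fee for chemotherapy, base: 36.1990950, min: 27.1493213, max: 45.2488688, dist: gamma_like}
        - {label: Administration fee for chemotherapy (monotherapy), base: 10.4072398, min: 7.80542986, max: 13.0090498, dist: gamma_like}
        - {label: Outpatient service fee, base: 6.60633484, min: 4.95475113, max: 8.25791855, dist: gamma_like}
        - {label: Prescription fee, base: 3.80090498, min: 2.85067873, max: 4.75113122, dist: gamma_like}
        - {label: Costs for management of complication (monotherapy), base: 28.7519014, min: 21.5639261, max: 35.9398768, dist: gamma_like}
      multiplicities:
        TAS-102: 1
        Administration fee for chemotherapy: 4
        Administration fee for chemotherapy (monotherapy): 4
        Outpatient service fee: 4
        Prescription fee: 4
  combination:
    transitions:
      progression: {base: 0.38191794, min: 0.28643845, max: 0.47739742, dist: beta_like}
      death: {base: 0.18161864, min: 0.13621398, max: 0.2270233, dist: beta_like}
      complication: {base: 0.0846049, min: 0.06345368, max: 0.10575613, dist: beta_like}
    utilities:
      stable: {base: 0.72, min: 0.54, max: 0.9, dist: beta_like}
      complication: {base: 0.72, min: 0.54, max: 0.9, dist: beta_like}
      progression: {base: 0.59, min: 0.4425, max: 0.7375, dist: beta_like}
      progression_complication: {base: 0.59, min: 0.4425, max: 0.7375, dist: beta_like}
      death: {base: 0.0, min: 0.0, max: 0.0, dist: beta_like}
    costs:
      exchange_rate_jpy_per_usd: 110.05
      body_weight_kg: 65.0
      body_surface_area_m2: 1.72
      complication_item: Costs for management of complication (combination)
      items:
        - {label: TAS-102, base: 1833.66516, min: 1375.24887, max: 2292.08145, dist: gamma_like}
        - {label: Bevacizumab, base: 767.945701, min: 575.959276, max: 959.932127, dist: gamma_like}
        - {label: IV drip fee, base: 65.6108597, min: 49.2081448, max: 82.0135747, dist: gamma_like}
        - {label: Administration fee for chemotherapy, base: 36.1990950, min: 27.1493213, max: 45.2488688, dist: gamma_like}
        - {label: Administration fee for chemotherapy (combination), base: 220.633484, min: 165.475113, max: 275.791855, dist: gamma_like}
        - {label: Outpatient service fee, base: 6.60633484, min: 4.95475113, max: 8.25791855, dist: gamma_like}
        - {label: Prescription fee, base: 3.80090498, min: 2.85067873, max: 4.75113122, dist: gamma_like}
        - {label: Costs for management of complication (combination), base: 72.0921038, min: 54.0690778, max: 90.1151297, dist: gamma_like}
      multiplicities:
        TAS-102: 1
        Bevacizumab: 2
        IV drip fee: 0
        Administration fee for chemotherapy: 4
        Administration fee for chemotherapy (combination): 1
        Outpatient service fee: 2
        Prescription fee: 2
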