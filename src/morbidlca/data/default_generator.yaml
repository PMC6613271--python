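# Default six-class synthetic ICU cohort configuration.
#
# Values tagged "[ref]" are fixed reference targets of the generator: they
# define the canonical subgroup structure (mixing proportions, signature
# class-conditional prevalences, subgroup mean ages, per-class outcome-rate
# extremes) that recovery tests and the acceptance harness measure against.
# All untagged prevalence cells and rates are fillers chosen to (a) respect
# the qualitative subgroup profiles (near-zero morbidity in "young",
# pulmonary disease anchored in class 1, arrhythmia/valvular disease in
# class 6, diabetic nephropathy in class 4) and (b) keep the six classes
# identifiable at the stated mixing proportions, which requires low
# background rates for each class's signature diseases (see
# docs/methods.md). Fillers are not recovery targets. Do not retune
# reference values; they are the ground truth of the simulation study.
#
# Class order everywhere:
#   1 cardiopulmonary, 2 young, 3 hepatic_addiction,
#   4 complicated_diabetics, 5 uncomplicated_diabetics, 6 cardiac

class_names:
  - cardiopulmonary
  - young
  - hepatic_addiction
  - complicated_diabetics
  - uncomplicated_diabetics
  - cardiac

# [ref] all six mixing proportions (sum to 1)
mixing: [0.061, 0.235, 0.098, 0.094, 0.248, 0.264]

age:
  # [ref] mean: cardiopulmonary 72.3, hepatic_addiction 52.25
  mean: [72.3, 36.0, 52.25, 65.0, 68.0, 78.0]
  # sd for hepatic_addiction derived from its reported mean-age 95% CI
  # half-width (0.40) at the class size implied by mixing * 36390
  sd: [6.5, 11.0, 12.2, 13.0, 12.0, 8.5]
  min: 16.0

# probability of elective (non-emergency) admission per class;
# [ref] uncomplicated_diabetics 0.357
elective_prob: [0.10, 0.15, 0.08, 0.12, 0.357, 0.12]

outcome_rates:
  # [ref] extremes: young 0.196 (min), hepatic_addiction 0.69 (max)
  organ_dysfunction: [0.45, 0.196, 0.69, 0.55, 0.25, 0.45]
  # marginal sepsis rate per class; sepsis is a sub-event of organ
  # dysfunction, so each entry must not exceed the rate above
  # [ref] extremes: young 0.125 (min), hepatic_addiction 0.467 (max)
  sepsis: [0.40, 0.125, 0.467, 0.40, 0.20, 0.38]
  # mortality among organ-dysfunction patients (marginal over sepsis status)
  # [ref] extremes: young 0.084 (min), hepatic_addiction 0.238 (max)
  mortality_given_organ_dysfunction: [0.19, 0.084, 0.238, 0.20, 0.10, 0.18]
  # mortality among sepsis patients
  # [ref] extremes: young 0.117 (min), hepatic_addiction 0.274 (max)
  mortality_given_sepsis: [0.21, 0.117, 0.274, 0.23, 0.12, 0.20]
  # mortality among patients without organ dysfunction
  mortality_baseline: [0.05, 0.01, 0.06, 0.05, 0.03, 0.05]

severity:
  # optional class-shifted severity scores (first-24h SOFA / OASIS analogs);
  # hepatic_addiction highest, complicated_diabetics second
  sofa_mean: [4.2, 2.5, 6.5, 6.0, 3.0, 4.0]
  sofa_sd: 2.5
  oasis_mean: [36.0, 26.0, 40.0, 39.0, 30.0, 37.0]
  oasis_sd: 8.0

# class-conditional Bernoulli prevalence per Elixhauser category,
# one row per category, six columns in class order
prevalence:
  congestive_heart_failure:   [0.70, 0.010, 0.10, 0.35, 0.12, 0.45]
  cardiac_arrhythmias:        [0.40, 0.020, 0.10, 0.25, 0.20, 0.75]
  valvular_disease:           [0.12, 0.010, 0.05, 0.10, 0.08, 0.38]
  pulmonary_circulation:      [0.35, 0.005, 0.03, 0.05, 0.02, 0.02]
  peripheral_vascular:        [0.25, 0.005, 0.03, 0.15, 0.08, 0.10]
  hypertension_uncomplicated: [0.45, 0.040, 0.25, 0.30, 0.70, 0.60]
  hypertension_complicated:   [0.05, 0.002, 0.02, 0.60, 0.05, 0.06]
  paralysis:                  [0.02, 0.010, 0.02, 0.03, 0.02, 0.05]
  other_neurological:         [0.08, 0.030, 0.08, 0.08, 0.06, 0.18]
  chronic_pulmonary:          [0.9386, 0.015, 0.03, 0.04, 0.04, 0.02]  # [ref] c1=0.9386
  diabetes_uncomplicated:     [0.15, 0.020, 0.12, 0.50, 0.70, 0.25]
  diabetes_complicated:       [0.04, 0.002, 0.02, 0.354, 0.06, 0.04]  # [ref] c4=0.354
  hypothyroidism:             [0.10, 0.010, 0.05, 0.10, 0.12, 0.12]
  renal_failure:              [0.15, 0.005, 0.08, 0.883, 0.05, 0.12]  # [ref] c4=0.883
  liver_disease:              [0.03, 0.010, 0.67, 0.05, 0.02, 0.02]   # [ref] c3=0.67
  peptic_ulcer:               [0.01, 0.003, 0.03, 0.02, 0.01, 0.01]
  aids_hiv:                   [0.002, 0.008, 0.02, 0.003, 0.002, 0.001]
  lymphoma:                   [0.02, 0.005, 0.01, 0.02, 0.01, 0.02]
  metastatic_cancer:          [0.04, 0.010, 0.03, 0.03, 0.02, 0.03]
  solid_tumor:                [0.06, 0.020, 0.05, 0.05, 0.04, 0.06]
  rheumatoid_arthritis:       [0.04, 0.010, 0.02, 0.04, 0.04, 0.04]
  coagulopathy:               [0.08, 0.020, 0.4181, 0.15, 0.04, 0.08] # [ref] c3=0.4181
  obesity:                    [0.15, 0.030, 0.04, 0.10, 0.12, 0.04]
  weight_loss:                [0.18, 0.020, 0.10, 0.08, 0.03, 0.05]
  fluid_electrolyte:          [0.45, 0.080, 0.30, 0.40, 0.15, 0.25]
  blood_loss_anemia:          [0.02, 0.010, 0.03, 0.03, 0.01, 0.02]
  deficiency_anemia:          [0.22, 0.040, 0.10, 0.20, 0.10, 0.10]
  alcohol_abuse:              [0.05, 0.040, 0.4775, 0.03, 0.02, 0.02] # [ref] c3=0.4775
  drug_abuse:                 [0.03, 0.040, 0.182, 0.02, 0.01, 0.01]  # [ref] c3=0.182
  depression:                 [0.10, 0.040, 0.201, 0.08, 0.08, 0.06]  # [ref] c3=0.201

# ICD-9 codes emitted into the diagnosis table when a category is active.
# Every code maps back to exactly its own category under the bundled code
# table, so code -> indicator round-trips are exact.
emission_codes:
  congestive_heart_failure: ["4280"]
  cardiac_arrhythmias: ["42731"]
  valvular_disease: ["4240"]
  pulmonary_circulation: ["4160"]
  peripheral_vascular: ["4439"]
  hypertension_uncomplicated: ["4019"]
  hypertension_complicated: ["4059"]
  paralysis: ["3449"]
  other_neurological: ["3320"]
  chronic_pulmonary: ["49390"]
  diabetes_uncomplicated: ["25000"]
  diabetes_complicated: ["25040"]
  hypothyroidism: ["2449"]
  renal_failure: ["5859"]
  liver_disease: ["5715"]
  peptic_ulcer: ["5319"]
  aids_hiv: ["042"]
  lymphoma: ["20280"]
  metastatic_cancer: ["1970"]
  solid_tumor: ["1629"]
  rheumatoid_arthritis: ["7140"]
  coagulopathy: ["2860"]
  obesity: ["27800"]
  weight_loss: ["2639"]
  fluid_electrolyte: ["2761"]
  blood_loss_anemia: ["2800"]
  deficiency_anemia: ["2811"]
  alcohol_abuse: ["30390"]
  drug_abuse: ["30490"]
  depression: ["311"]

# codes emitted for drawn acute outcomes; none of these maps to any
# Elixhauser category (keeps the chronic-indicator round-trip exact)
outcome_emission:
  organ_dysfunction: ["5845"]   # acute kidney failure with tubular necrosis
  infection: ["0389"]           # septicemia, unspecified

n: 36390
seed: 12345
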