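# Default synthetic-survey specification emulating the 412-respondent
# healthcare-professional survey. Category counts follow the published
# demographic table (counts renormalized where the printed column exceeds
# n=412); education bands are split across the finer weight-map categories
# and the experience-band distribution, absent from the publication, is a
# fixed mid-career default (see docs/methods.md). Item modes are the printed
# preferred responses; the first question block uses a 1-6 agreement scale,
# the remaining blocks 1-5.
name: pandemic-survey-default
n_respondents: 412
seed: 20220127
category_counts:
  education_level:
    health_assistant: 24.5
    medical_assistant: 24.5
    resident: 36
    specialist_or_pharmacist: 109
    primary_doctor_or_pharmacist: 109
    phd_academic: 109
  experience_band:
    "0-4": 62
    "5-9": 82
    "10-14": 103
    "15-19": 82
    "20+": 83
  pandemic_role:
    not_involved_or_education: 132
    dsp_ministry_pharmacy_ngo: 58
    triage_or_vaccination: 103
    civil_hospital: 37
    covid_support_hospital_er_ambulance: 82
  profession:
    doctor: 329
    pharmacist: 38
    medical_assistant: 49
  sector:
    private: 57
    civil: 169
    public_order_security: 186
  sex:
    male: 144
    female: 268
items:
  - {item_id: Q1.1, scale_max: 6, mode: 4, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q1.2, scale_max: 6, mode: 4, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q1.3, scale_max: 6, mode: 5, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q1.4, scale_max: 6, mode: 6, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q1.5, scale_max: 6, mode: 6, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q1.6, scale_max: 6, mode: 5, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q1.7, scale_max: 6, mode: 5, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q1.12, scale_max: 6, mode: 4, concentration: 2.0, missing_prob: 0.02}
  - {item_id: Q2.1, scale_max: 5, mode: 4, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.2, scale_max: 5, mode: 3, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.3, scale_max: 5, mode: 5, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.4, scale_max: 5, mode: 5, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.5, scale_max: 5, mode: 4, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.6, scale_max: 5, mode: 4, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.7, scale_max: 5, mode: 4, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.8, scale_max: 5, mode: 3, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q2.10, scale_max: 5, mode: 3, concentration: 2.0, missing_prob: 0.10}
  - {item_id: Q3.1, scale_max: 5, mode: 5, concentration: 2.0, missing_prob: 0.05}
  - {item_id: Q3.3, scale_max: 5, mode: 5, concentration: 2.0, missing_prob: 0.05}
  - {item_id: Q3.4, scale_max: 5, mode: 5, concentration: 2.0, missing_prob: 0.05}
  - {item_id: Q3.5, scale_max: 5, mode: 2, concentration: 2.0, missing_prob: 0.05}
  - {item_id: Q3.8, scale_max: 5, mode: 5, concentration: 2.0, missing_prob: 0.05}
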