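# Reference six-factor pattern-loading solution for the 36-item
# responsiveness & respectful-treatment questionnaire (29 items retained).
# These are the published calibration weights of the instrument and the
# default weights for scoring; a freshly estimated solution can be used
# interchangeably through the same file format.
spec_version: "1"
factors:
  - name: "Communication & supportive care"
    items:
      - {id: intro_name, loading: 0.55}
      - {id: explain_done, loading: 0.82}
      - {id: permission_vaginal_exam, loading: 0.82}
      - {id: explain_procedures, loading: 0.86}
      - {id: explain_medicine, loading: 0.84}
      - {id: could_ask_questions, loading: 0.66}
      - {id: talk_feelings, loading: 0.78}
      - {id: address_fears, loading: 0.51}
      - {id: encouraged_walk, loading: 0.53}
      - {id: encouraged_eat_drink, loading: 0.50}
      - {id: paid_attention, loading: 0.55}
  - name: "Hospital environment"
    items:
      - {id: hospital_clean, loading: 0.54}
      - {id: clean_water, loading: 0.88}
      - {id: drinking_water, loading: 0.91}
  - name: "Maintained respect & dignity"
    items:
      - {id: treated_respect, loading: 0.45}
      - {id: treated_friendly, loading: 0.45}
      - {id: waiting_time, loading: 0.53}
      - {id: shouted_screamed, loading: 0.83}
      - {id: mocked, loading: 1.09}
      - {id: best_care, loading: 0.46}
      - {id: recommend_hospital, loading: 0.45}
  - name: "Social support"
    items:
      - {id: companion_labour, loading: 0.85}
      - {id: companion_birth, loading: 0.94}
  - name: "Maintained privacy & confidentiality"
    items:
      - {id: info_shared, loading: 1.02}
      - {id: privacy_violated, loading: 0.67}
  - name: "Lack of physical & verbal abuse"
    items:
      - {id: slapped_pinched, loading: 0.40}
      - {id: negative_comments, loading: 0.66}
      - {id: shouted_items, loading: 0.78}
      - {id: bribe_request, loading: -0.73}
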