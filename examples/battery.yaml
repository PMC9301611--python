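name: synthetic-14
age_bands:
- - 5
  - 7
- - 7
  - 9
- - 9
  - 13
- - 13
  - 16
- - 16
  - 21
subtests:
- name: visual_processing
  ability: Gv
  loading: 0.72
  reliability: 0.87
  retest: 0.8
- name: visual_processing_2
  ability: Gv
  loading: 0.7
  reliability: 0.86
  retest: 0.78
- name: processing_speed
  ability: Gs
  loading: 0.58
  reliability: 0.88
  retest: 0.8
- name: processing_speed_2
  ability: Gs
  loading: 0.5599999999999999
  reliability: 0.87
  retest: 0.78
- name: auditory_memory
  ability: Gsm
  loading: 0.68
  reliability: 0.84
  retest: 0.8
- name: auditory_memory_2
  ability: Gsm
  loading: 0.66
  reliability: 0.83
  retest: 0.78
- name: spatial_memory
  ability: Gsm
  loading: 0.66
  reliability: 0.83
  retest: 0.8
- name: spatial_memory_2
  ability: Gsm
  loading: 0.64
  reliability: 0.82
  retest: 0.78
- name: long_term_memory
  ability: Glr
  loading: 0.7
  reliability: 0.85
  retest: 0.8
- name: long_term_memory_2
  ability: Glr
  loading: 0.6799999999999999
  reliability: 0.84
  retest: 0.78
- name: abstract_reasoning
  ability: Gf
  loading: 0.78
  reliability: 0.9
  retest: 0.8
- name: abstract_reasoning_2
  ability: Gf
  loading: 0.76
  reliability: 0.89
  retest: 0.78
- name: verbal_reasoning
  ability: Gc
  loading: 0.74
  reliability: 0.89
  retest: 0.8
- name: verbal_reasoning_2
  ability: Gc
  loading: 0.72
  reliability: 0.88
  retest: 0.78
composites:
- name: EBIQ14
  members:
  - visual_processing
  - visual_processing_2
  - processing_speed
  - processing_speed_2
  - auditory_memory
  - auditory_memory_2
  - spatial_memory
  - spatial_memory_2
  - long_term_memory
  - long_term_memory_2
  - abstract_reasoning
  - abstract_reasoning_2
  - verbal_reasoning
  - verbal_reasoning_2
  clip_range:
  - 55
  - 145
  retest: 0.9
- name: FSIQ7
  members:
  - visual_processing
  - processing_speed
  - auditory_memory
  - spatial_memory
  - long_term_memory
  - abstract_reasoning
  - verbal_reasoning
  clip_range:
  - 55
  - 145
  retest: 0.88
- name: ABIQ2
  members:
  - abstract_reasoning
  - verbal_reasoning
  clip_range:
  - 55
  - 145
  retest: 0.84
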