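n_subjects: 60
seed: 20150730
mixture:
  type1_case: 6
  type2_case: 6
  type3_case: 6
  phenocopy: 6
  young_aaa: 6
  single_code_aaa: 6
  nonspecialty_aaa: 6
  stale_record: 6
  clean_control: 6
  noisy_control: 6
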