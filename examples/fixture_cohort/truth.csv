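subject_id,archetype,expected_label,expected_case_type,expected_exclusion_reason,true_case,perturbed
S0001,type1_case,case,1,,True,False
S0002,type1_case,case,1,,True,False
S0003,type1_case,case,1,,True,False
S0004,type1_case,case,1,,True,False
S0005,type1_case,case,1,,True,False
S0006,type1_case,case,1,,True,False
S0007,type2_case,case,2,,True,False
S0008,type2_case,case,2,,True,False
S0009,type2_case,case,2,,True,False
S0010,type2_case,case,2,,True,False
S0011,type2_case,case,2,,True,False
S0012,type2_case,case,2,,True,False
S0013,type3_case,case,3,,True,False
S0014,type3_case,case,3,,True,False
S0015,type3_case,case,3,,True,False
S0016,type3_case,case,3,,True,False
S0017,type3_case,case,3,,True,False
S0018,type3_case,case,3,,True,False
S0019,phenocopy,excluded,,phenocopy,False,False
S0020,phenocopy,excluded,,phenocopy,False,False
S0021,phenocopy,excluded,,phenocopy,False,False
S0022,phenocopy,excluded,,phenocopy,False,False
S0023,phenocopy,excluded,,phenocopy,False,False
S0024,phenocopy,excluded,,phenocopy,False,False
S0025,young_aaa,excluded,,aaa_onset_at_or_under_min_age,False,False
S0026,young_aaa,excluded,,aaa_onset_at_or_under_min_age,False,False
S0027,young_aaa,excluded,,aaa_onset_at_or_under_min_age,False,False
S0028,young_aaa,excluded,,aaa_onset_at_or_under_min_age,False,False
S0029,young_aaa,excluded,,aaa_onset_at_or_under_min_age,False,False
S0030,young_aaa,excluded,,aaa_onset_at_or_under_min_age,False,False
S0031,single_code_aaa,excluded,,unconfirmed_aaa_code,False,False
S0032,single_code_aaa,excluded,,unconfirmed_aaa_code,False,False
S0033,single_code_aaa,excluded,,unconfirmed_aaa_code,False,False
S0034,single_code_aaa,excluded,,unconfirmed_aaa_code,False,False
S0035,single_code_aaa,excluded,,unconfirmed_aaa_code,False,False
S0036,single_code_aaa,excluded,,unconfirmed_aaa_code,False,False
S0037,nonspecialty_aaa,excluded,,unconfirmed_aaa_code,False,False
S0038,nonspecialty_aaa,excluded,,unconfirmed_aaa_code,False,False
S0039,nonspecialty_aaa,excluded,,unconfirmed_aaa_code,False,False
S0040,nonspecialty_aaa,excluded,,unconfirmed_aaa_code,False,False
S0041,nonspecialty_aaa,excluded,,unconfirmed_aaa_code,False,False
S0042,nonspecialty_aaa,excluded,,unconfirmed_aaa_code,False,False
S0043,stale_record,excluded,,no_recent_encounter,False,False
S0044,stale_record,excluded,,no_recent_encounter,False,False
S0045,stale_record,excluded,,no_recent_encounter,False,False
S0046,stale_record,excluded,,no_recent_encounter,False,False
S0047,stale_record,excluded,,no_recent_encounter,False,False
S0048,stale_record,excluded,,no_recent_encounter,False,False
S0049,clean_control,control,,,False,False
S0050,clean_control,control,,,False,False
S0051,clean_control,control,,,False,False
S0052,clean_control,control,,,False,False
S0053,clean_control,control,,,False,False
S0054,clean_control,control,,,False,False
S0055,noisy_control,control,,,False,False
S0056,noisy_control,control,,,False,False
S0057,noisy_control,control,,,False,False
S0058,noisy_control,control,,,False,False
S0059,noisy_control,control,,,False,False
S0060,noisy_control,control,,,False,False
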