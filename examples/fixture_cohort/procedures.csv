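subject_id,event_date,cpt_code,clinic,age_at_event
S0001,2005-05-08,34825,Vascular Surgery,72
S0002,2009-01-19,35081,Vascular Surgery,62
S0003,2005-02-24,34802,Vascular Surgery,51
S0004,2010-06-12,35102,Vascular Surgery,71
S0005,2009-11-16,35082,Vascular Surgery,62
S0006,2012-11-13,34804,Vascular Surgery,68
S0049,2009-05-24,36415,Family Practice,58
S0052,2009-07-18,99213,Family Practice,65
S0055,2004-08-16,36415,Cardiology,66
S0055,2004-01-06,93000,Internal Medicine,65
S0055,2007-03-13,99213,Internal Medicine,69
S0056,2011-04-02,99213,Emergency Medicine,67
S0057,2009-10-21,80053,Internal Medicine,60
S0058,2007-08-11,36415,Cardiology,47
S0058,2007-02-13,99214,Cardiology,46
S0058,2010-10-31,36415,Emergency Medicine,50
S0059,2012-11-17,99214,Emergency Medicine,56
S0059,2012-07-11,93000,Internal Medicine,56
S0060,2007-08-12,99214,Emergency Medicine,65
S0060,2013-01-20,80053,Internal Medicine,71
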