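subject_id,label,age_at_mri,age_at_onset,febrile,age_at_surgery,seizure_freq_per_month,followup_months,ilae
F01,1,35,2,0,36,4,38,1
F02,1,64,14,0,64,3,48,1
F03,1,22,0,0,23,30,25,1
F04,1,49,2,1,49,1,39,1
F05,1,39,29,0,39,3,36,1
F06,1,44,15,0,44,4,13,1
F07,1,45,21,0,46,15,24,1
F08,1,42,9,0,42,60,28,1
F09,1,27,13,1,27,2,12,1
F10,1,30,18,1,31,5,12,1
F11,1,33,13,0,34,2,24,2
F12,1,45,3,1,46,3,12,1
F13,1,48,30,0,49,15,12,1
F14,1,22,13,0,22,4,29,1
F15,1,32,29,0,32,8,18,2
F16,1,54,14,0,54,1,12,1
F17,1,39,36,0,40,4,17,2
F18,1,29,15,1,29,6,12,2
F19,-1,24,6,0,26,1,38,3
F20,-1,25,11,1,25,5,54,3
F21,-1,33,32,0,33,10,52,3
F22,-1,32,6,1,32,7,34,4
F23,-1,56,33,0,57,1,16,4
F24,-1,43,1,0,43,2,22,4
F25,-1,23,13,0,24,1,23,4
F26,-1,26,9,0,26,4,12,3
F27,-1,50,15,1,51,6,23,4
F28,-1,70,34,0,72,6,12,3
F29,-1,41,11,1,41,3,16,4
F30,-1,62,21,0,63,2,12,3
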