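subject_id,label,age_at_mri,age_at_onset,febrile,age_at_surgery,seizure_freq_per_month,followup_months,ilae
M01,1,56,24,1,56,3,24,1
M02,1,51,33,0,51,3,24,1
M03,1,53,1,0,52,6,18,1
M04,1,32,13,1,32,4,16,2
M05,1,41,5,0,42,3,30,1
M06,1,57,34,0,57,20,13,1
M07,1,50,26,0,50,5,26,1
M08,1,22,1,0,23,12,23,1
M09,1,31,3,1,31,1,19,2
M10,1,27,18,1,28,5,12,1
M11,1,37,35,0,37,10,19,1
M12,-1,67,46,0,67,40,12,4
M13,-1,47,5,1,47,4,45,3
M14,-1,21,18,0,21,4,12,3
M15,-1,49,15,1,50,1,30,3
M16,-1,46,3,1,46,8,28,4
M17,-1,44,11,0,45,3,12,4
M18,-1,51,5,0,51,5,25,4
M19,-1,51,42,1,52,5,20,3
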