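subject_id,label,decision_value
M01,1,0.75914
M02,1,0.075861
M03,1,0.4679
M04,1,0.059285
M05,1,0.43343
M06,1,0.67053
M07,1,1.0851
M08,1,0.73569
M09,1,0.65359
M10,1,0.19013
M11,1,0.92097
M12,-1,-1.2076
M13,-1,-0.097875
M14,-1,-0.60293
M15,-1,-0.20462
M16,-1,-0.59343
M17,-1,-0.63184
M18,-1,-0.023385
M19,-1,0.55178
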