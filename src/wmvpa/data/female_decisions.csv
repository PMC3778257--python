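subject_id,label_printed,label,decision_value
F01,1,1,0.69374
F02,1,1,0.057686
F03,1,1,0.61948
F04,1,1,0.31212
F05,1,1,0.54516
F06,1,1,0.62866
F07,1,1,0.78818
F08,1,1,0.14086
F09,1,1,0.3572
F10,1,1,0.66793
F11,1,1,1.2308
F12,1,1,0.54714
F13,1,1,0.52743
F14,1,1,0.3758
F15,1,1,1.9909
F16,1,1,0.26292
F17,1,1,0.95757
F18,1,1,0.87285
F19,1,-1,-0.46047
F20,-1,-1,-0.020884
F21,-1,-1,-0.18794
F22,-1,-1,0.35073
F23,-1,-1,-0.1866
F24,-1,-1,-0.18786
F25,-1,-1,-0.085392
F26,-1,-1,-0.086466
F27,-1,-1,-0.29476
F28,-1,-1,-0.19536
F29,-1,-1,-0.3722
F30,-1,-1,-0.21038
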