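key,measure_height_cm,a,b
Acacia,130,-2.35,2.42
Acacia,50,-2.6,2.42
Acacia,10,-2.9,2.42
Eucalyptus,130,-2.2,2.47
Eucalyptus,50,-2.45,2.47
Eucalyptus,10,-2.75,2.47
other,130,-2.5,2.4
other,50,-2.75,2.4
other,10,-3.05,2.4
Acacia dealbata,130,-2.1,2.5
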