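#id=compound12
#precursor=1173.6
#charge=1
1059.1	55.0
929.3	60.0
815.4	70.0
685.3	65.0
528.3	80.0
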