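#id=cosmomycinD
#precursor=1189.6
#charge=1
1189.6	20.0
1075.5	55.0
945.3	60.0
831.3	70.0
701.3	65.0
595.3	100.0
544.3	80.0
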