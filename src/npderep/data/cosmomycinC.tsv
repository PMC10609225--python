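#id=cosmomycinC
#precursor=1173.3
#charge=1
1059.1	55.0
945.1	60.0
831.2	70.0
701.2	65.0
544.3	80.0
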