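name	delta_mass
O	15.9949
H2	2.0157
H2O	18.0106
CH2	14.0157
acetyl	42.0106
rho	114.068079
defuc	130.062994
RhN	157.110279
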