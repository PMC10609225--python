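name	formula	exact_mass	nominal_mass
rho	C6H10O2	114.068079	114
defuc	C6H10O3	130.062994	130
RhN	C8H15NO2	157.110279	157
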