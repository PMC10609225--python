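name	ion_mz	ion_formula	compound_class
cosmomycin D	1189.5878		anthracycline
cosmomycin C	1173.5925		anthracycline
cosmomycin B	772.3516		anthracycline
cosmomycin A	756.3598		anthracycline
hedamycin	747.3470		angucycline
kidamycin	689.3422		angucycline
dehydrocosmomycin D	1187.5710	C60H87N2O22	anthracycline
dehydrocosmomycin C	1171.5754	C60H87N2O21	anthracycline
A447 D	1171.5754	C60H87N2O21	anthracycline
A447 C	1157.5942	C60H89N2O20	anthracycline
beta-rhodomycin S-4	1075.5168	C54H79N2O20	anthracycline
cosmomycin C isomer	1173.5925	C60H89N2O21	anthracycline
dehydro-rho A447 C	1155.5762	C60H87N2O20	anthracycline
cosmocarcin C	754.3417	C40H52NO13	anthracycline
dehydroxycosmomycin A	740.3627		anthracycline
epoxykidamycin	705.3298	C39H49N2O10	angucycline
dehydrokidamycin	687.3245	C39H47N2O9	angucycline
saptomycin C1	717.3750	C41H53N2O9	angucycline
dihydrosaptomycin C1	719.3541	C41H55N2O9	angucycline
neopluramycin	731.3520	C41H51N2O10	angucycline
rubiflavin E	733.3668	C41H53N2O10	angucycline
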