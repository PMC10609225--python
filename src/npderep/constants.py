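"""Physical constants used throughout the package.

Monoisotopic element masses (Da), CODATA-consistent, 10 significant figures.
All ion arithmetic in the package is for positive even-electron cations
([M+H]+ / [M+2H]2+), so the proton and electron masses matter at the
sub-millidalton level.
"""

MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

PROTON_MASS: float = 1.007276466
ELECTRON_MASS: float = 0.000548579909
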