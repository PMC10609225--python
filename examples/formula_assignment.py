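"""Assign elemental formulas to accurate ion masses.

The measured [M+H]+ of epoxykidamycin is 705.3298; enumerating CHNOS
compositions within 15 ppm (the measurement is ~12 ppm off theory)
recovers the literature assignment C39H49N2O10 among the candidates.
"""

from npderep.formula import IonFormula, enumerate_formulas, rdbe, theoretical_mz

candidates = enumerate_formulas(705.3298, charge=1, ppm_tol=15.0)
print(f"{len(candidates)} CHNOS candidates within 15 ppm of m/z 705.3298")
print("rank  formula          theo m/z     ppm    RDBE")
for rank, c in enumerate(candidates[:8], start=1):
    marker = "  <- literature assignment" if c.formula.hill_string() == "C39H49N2O10" else ""
    print(f"{rank:4d}  {c.formula.hill_string():15s} {c.theo_mz:11.4f} {c.ppm_error:7.2f} {c.rdbe:6.1f}{marker}")

f = IonFormula.parse("C60H87N2O22")
print(f"\ntheoretical m/z of [C60H87N2O22]+ (dehydrocosmomycin D): "
      f"{theoretical_mz(f):.4f}  (reported 1187.5710, ~3 ppm), RDBE {rdbe(f)}")
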