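"""Dereplicate the cosmomycins from their printed MS2 fragment tables.

Anthracycline glycosides shed their deoxysugars one at a time under CID:
rhodinose (-114), 2-deoxy-L-fucose (-130) and finally the amino sugar
rhodosamine (-157). The chain of those neutral losses identifies the
glycan, and the [M+2H]2+ companion ion confirms the molecular ion.
"""

from npderep import datasets
from npderep.ladder import best_ladder, charge_companion_mz, detect_ladders, find_charge_companions, glycan_composition

for load, tol in [(datasets.cosmomycin_d_spectrum, 0.5),
                  (datasets.cosmomycin_c_spectrum, 0.5),
                  (datasets.compound12_spectrum, 0.75)]:
    s = load()
    ladder = best_ladder(detect_ladders(s, tol=tol, mode="nominal"))
    print(f"{s.id}: [M+H]+ {s.precursor_mz}")
    for step in ladder.steps:
        print(f"  {step.from_mz:8.1f} -> {step.to_mz:8.1f}   -{round(step.observed_delta):3d}  ({step.loss_name})")
    comp = ", ".join(f"{name} x{n}" for name, n in sorted(glycan_composition(ladder).items()))
    print(f"  terminal fragment {ladder.terminal_mz}, glycan composition: {comp}")

# the doubly protonated companion of cosmomycin D's molecular ion
print(f"\n[M+2H]2+ of 1189.5878 = {charge_companion_mz(1189.5878):.4f} (printed as 595.3)")
print("companion pairs found in the cosmomycin D table:",
      find_charge_companions(datasets.cosmomycin_d_spectrum(), tol=0.5))
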