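# npderep

Dereplication of glycosylated aromatic polyketides from tandem mass
spectrometry, plus the turbidometric plate statistic used to find the
producing strains in the first place.

Actinomycete extract screens routinely rediscover known compounds, so the
first computational task after a hit is *dereplication*: deciding from the
LC-MS/MS data which molecules are already known and which are putative new
analogs. For glycosylated anthracyclines and angucyclines (cosmomycins,
kidamycin and relatives) the decisive signal is the **deoxysugar
neutral-loss ladder**: under collision-induced dissociation the saccharide
chains peel off sugar by sugar, producing fragment cascades such as

    1189.6 → 1075.5 (−114, rhodinose) → 945.3 (−130, 2-deoxy-L-fucose)
           → 831.3 (−114) → 701.3 (−130) → 544.3 (−157, rhodosamine)

which identify the glycan composition even when the aglycone is unknown.
`npderep` implements that analysis as a tested, reusable pipeline:

* **spectra_io** — MGF and TSV peak-list reading/writing with canonical
  peak lists (sorted, de-duplicated, centroided).
* **network** — GNPS-style molecular networking, natively implemented:
  modified-cosine similarity (fragments match either directly or offset by
  the precursor-mass difference, scored by exact maximum-weight one-to-one
  matching) with the standard parameter set (min cosine 0.6, fragment
  tolerance 0.02 Da, ≥4 matched peaks, mutual top-10 edges, component size
  cap 100, minimum cluster size 2).
* **ladder** — depth-first detection of sugar neutral-loss ladders
  (−114/−130/−157 and dehydro variants) in nominal or monoisotopic mode,
  plus [M+2H]²⁺ charge-companion detection.
* **formula** — accurate-mass arithmetic for even-electron cations and
  exhaustive CHNOS formula enumeration with RDBE and H/C plausibility
  filters.
* **annotate** — seed-library matching by precursor mass and breadth-first
  analog propagation along network edges whose parent-mass difference
  matches a chemical transform (±O, ±H2, ±H2O, ±CH2, ±acetyl, ±sugar).
* **bioassay** — the microbroth screening statistic
  `inhibition % = [1 − (t24 − t0)/(C24 − C0)] × 100` on OD600 plate
  readings, control validation, triplicate aggregation and the strict
  \>60 % activity threshold.
* **simulate** — a ground-truthed generator of glycoside MS/MS spectra,
  analog families and screening plates, so every stage is testable without
  any instrument data.

## Worked example

```bash
python examples/ladder_dereplication.py
```

```
cosmomycinD: [M+H]+ 1189.6
    1189.6 ->   1075.5   -114  (rho)
    1075.5 ->    945.3   -130  (defuc)
     945.3 ->    831.3   -114  (rho)
     831.3 ->    701.3   -130  (defuc)
     701.3 ->    544.3   -157  (RhN)
  terminal fragment 544.3, glycan composition: RhN x1, defuc x2, rho x2

[M+2H]2+ of 1189.5878 = 595.2975 (printed as 595.3)
```

The five losses read off cosmomycin D's two trisaccharide chains (two
rhodinoses, two deoxyfucoses and the innermost rhodosamine); the terminal
m/z 544.3 is the doubly-deglycosylated aglycone-containing fragment, and
the half-mass companion at 595.3 confirms the [M+H]⁺ assignment. The other
examples show networking plus analog propagation
(`molecular_network.py`), formula assignment (`formula_assignment.py`,
which recovers C39H49N2O10 for the measured m/z 705.3298) and plate
screening (`plate_screening.py`).

A thin CLI mirrors the library for batch use:

```bash
npderep simulate --seed 3 --out sim/
npderep ladders sim/spectra.mgf --mode exact --tol 0.03
npderep network sim/spectra.mgf --out net/
npderep formulas --mz 705.3298 --ppm 15
npderep run --spectra-dir sim/ --out-dir results/
```

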