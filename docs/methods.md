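# Methods

## Scope and data model

`npderep` operates on centroided MS/MS peak lists (positive mode,
even-electron cations only: [M+H]⁺ and [M+2H]²⁺). Spectra are
canonicalized on construction — peaks sorted by ascending m/z, peaks
within 1e-6 Th merged by intensity sum — and all downstream algorithms
assume that canonical form. Profile-mode data, chromatograms,
retention-time alignment, isotope envelopes and negative mode are out of
scope. Intensities are optional: ladder detection is mass-only by design,
and a peak without an intensity defaults to 1.0.

## Modified cosine and network construction

Spectra are preprocessed the way molecular-networking pipelines do:
peaks within 17 Da of the precursor are removed, each peak must rank
among the 6 most intense within the 50-Da window centred on it, and
surviving intensities are square-root transformed and L2-normalized.

Two peaks (a, b) are match candidates when |mz_a − mz_b| ≤ τ_frag or when
|mz_a − mz_b − Δprecursor| ≤ τ_frag (τ_frag = 0.02 Da by default); the
score is the maximum-weight one-to-one matching over candidate pairs with
weight = product of normalized intensities. We solve the matching exactly
with the rectangular linear-sum assignment rather than the greedy pairing
some implementations use: candidate sets are tiny, the exact optimum is
deterministic and never smaller than greedy, and the test suite pins it
to an exhaustive-enumeration oracle on small spectra and to an
independent implementation (matchms) on simulated analog families.

Edges require score ≥ 0.6 and ≥ 4 matched peaks; an edge survives only if
it is in the top 10 by score for *both* endpoints; components larger than
100 nodes are reduced by repeatedly deleting their lowest-score edge; and
components below the minimum cluster size (2) are dropped from the
reported network. All parameters are exposed (`NetworkParams`) and edge
tables are emitted deterministically (sorted, fixed formatting), so a
rerun is byte-identical.

Pairs with large parent-mass differences are still scored (no
short-circuit): analog clusters can span ~90 Da or more of mass range.

## Deoxysugar neutral-loss ladders

The loss library holds the glycosidic-loss residues of the relevant
deoxysugars, with masses computed from the element table rather than
copied from the literature's rounded values:

| residue | formula of the loss | monoisotopic (Da) | nominal |
|---|---|---|---|
| rhodinose (rho) | C6H10O2 | 114.068079 | 114 |
| 2-deoxy-L-fucose (defuc) | C6H10O3 | 130.062994 | 130 |
| rhodosamine (RhN) | C8H15NO2 | 157.110279 | 157 |

Dehydro variants (residue − H2) are available behind a flag for analogs
carrying a double bond in a sugar.

Detection is a depth-first search rooted at the precursor m/z (or the
most intense peak within tolerance of it). At each level every residue is
tried against every unused peak within tolerance of `current − residue`
(closest first); every maximal root-to-leaf path with ≥1 step becomes a
ladder, and ladders are sorted by (steps descending, summed |mass error|
ascending), which makes `best_ladder` deterministic.

Two matching modes exist because literature fragment tables print masses
to one decimal against integer losses, while measured spectra support
monoisotopic matching. Nominal mode with tol 0.5 Da reproduces the
cosmomycin D and C cascades; the cosmomycin C isomer's table needs
0.75 Da because its printed first step (1173.6 → 1059.1) is a 114.5 Da
observed loss — the printed roundings are internally inconsistent, so the
tolerance is a per-call parameter.

**Identifiability.** When a compound carries two chains, fragments from
both peel orders coexist, and the fragment union generally supports
several step sequences with identical residue *composition*. MS2 alone
cannot assign a sugar to a particular chain position, so the package
treats the glycan composition (the multiset of losses) as the recoverable
quantity; the reported sequence is the lowest-error parse. Annotation
strings likewise report residue mass classes, not positional identities:
a −114 step may be rhodinose or any mass-identical dehydroxylated sugar.

## Formula enumeration

Ion formulas are written with their charge-carrying protons included
(C60H87N2O22 with z = 1 *is* the protonated molecule). Theoretical m/z is
(Σ atom masses − z·m_e)/z; the electron mass (0.00055 Da) is below the
reporting precision of typical measurements but subtracting it is the
physically correct convention. Enumeration scans C ≤ 70, H ≤ 130, N ≤ 6,
O ≤ 26, S ≤ 2 (defaults), solving the hydrogen count analytically per
(C, N, O, S) cell, and filters by RDBE ∈ [0, 40] and 0.2 ≤ H/C ≤ 3.2 for
carbon-containing ions. A test equates the solver with an unpruned numpy
lattice scan. Reported experimental masses can sit 10+ ppm from theory,
so tolerance is caller-chosen; they are treated as measurements, never as
calibration truth. Sulfur is included for generality although the
compound classes at issue are CHNO. Isotope-pattern scoring and database
lookups are out of scope.

## Seed matching and analog propagation

Nodes are matched to a seed library (bundled: the cosmomycins, hedamycin,
kidamycin and their reported derivatives with printed [M+H]⁺ masses) by
nearest precursor mass within 0.02 Da, ties broken by smaller |Δ| then
library order. Analog labels then propagate breadth-first (default ≤2
hops): an unannotated neighbour is labelled when the edge's parent-mass
delta matches one transform (±O 15.9949, ±H2 2.0157, ±H2O 18.0106,
±CH2 14.0157, ±acetyl 42.0106, or a whole deoxysugar residue) within
0.01 Da. Shortest hops win; equal hops resolve by smallest |delta error|;
no node ever carries two labels. The propagation tolerance is
deliberately tighter than the networking parent-mass tolerance because
neighbouring transform masses must remain discriminable; 0.01 Da matches
the four-decimal precision at which such mass-difference reasoning is
done manually. Sums of two transforms are supported behind a flag but
disabled by default — single deltas explain every bundled assignment.
Each matched transform also reports its integer nominal delta (16, 2,
114, …) for literature-style reporting.

## Plate screening statistic

Plates are 12 rows × 8 columns in this assay's orientation (row 1: four
sterility wells and four levofloxacin positive controls; rows 2–11: test
extracts; row 12: negative controls). For a test well,

    inhibition % = [1 − (t24 − t0)/(C24 − C0)] × 100

where C is the plate's own negative-control growth, aggregated as the
mean of the row-12 wells (median behind a flag; the combiner is not
dictated by the assay description). Values are not clamped: >100 %
indicates lysis, <0 % growth promotion. A plate is invalid if any
sterility well grows by more than 0.05 OD or the mean positive-control
inhibition falls below the activity threshold. Replicates (three by
design) are combined by the mean of per-replicate inhibitions, each
computed against its own plate's controls, and a well is *active* only
when the mean is strictly above 60 %. The boundary case (exactly 60.0) is
inactive and tested.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes:

* **Glycoside spectra.** An aglycone (uniform 350–600 Da) carries two
  trisaccharide chains (innermost rhodosamine, outer sugars drawn from
  rhodinose/deoxyfucose). Fragments are emitted for both chain-peel
  orders, with Gaussian m/z jitter (σ = 0.01 Da default), geometric
  intensity decay (ratio 0.7) down the ladder, an [M+2H]²⁺ companion with
  probability 0.5, and 20 uniform noise peaks capped at twice the weakest
  true peak. The intensity model is invented — real intensity patterns
  are compound- and instrument-specific — and ladder detection must not
  depend on it; a flag randomizes intensities and a test verifies the
  detected ladder is unchanged.
* **Analog families.** A parent plus analogs differing by one signed
  transform applied to the aglycone, so the family shares its ladder
  topology and links up under the modified cosine.
* **Plates.** Control ΔOD ~ Normal(0.45, 0.03) truncated at zero; test
  ΔOD = (control draw)·(1 − effect) + Normal(0, 0.01); triplicate plates;
  truth tables record every effect.

Everything is deterministic under a fixed seed, and generated MGF files
round-trip through the reader unchanged.

**What passing the synthetic benchmarks shows.** At the default noise
levels, ladder detection recovers a full-length ladder with the true
glycan composition in ≥95 % of spectra (200 trials), analog propagation
recovers ≥90 % of true labels with zero wrong transform assignments at
σ = 0.003 Da precursor noise (100 families), and the screening statistic
separates 0 %- from 80 %-effect wells with sensitivity and specificity
≥0.99 across ~560 triplicate calls. These are statements about data with
this generator's simplifications — no chimeric spectra, no co-eluting
isomers, no retention-time structure, no isotope envelopes, well-behaved
baseline OD — and say nothing about recall on real instrument runs.

**A known tension.** The invented intensity model fixes the
noise-to-signal intensity ratio of a simulated spectrum at ≈0.57
(20 noise peaks with mean intensity equal to the weakest true fragment,
against a fragment intensity sum of ≈4.1). Because unmatched intensity
enters the cosine normalization, attainable modified-cosine scores
between family members are capped around 0.55–0.68, straddling the 0.6
edge threshold, so whole-family clustering at the default threshold is
not reliable on these synthetic spectra (verified against an independent
cosine implementation; it is a property of the generator's intensity
model, not of the scoring code). The clustering mechanics are therefore
demonstrated on noise-free simulations, where families cluster exactly
and unrelated spectra stay unconnected.

## Numerical conventions

Element masses are fixed CODATA-style constants to 10 significant
figures (C exactly 12). Ties everywhere break deterministically (peak
ties by smaller mass difference then lower m/z; seed ties by library
order; edge ordering by score, then |Δ parent mass|, then node ids), so
identical inputs give byte-identical outputs. Degenerate inputs — empty
spectra, zero-intensity spectra, empty networks, empty plates — return
empty results rather than raising, except where the input is invalid
(non-growing negative control, missing wells, malformed records), which
raises with a message naming the offending record or well.

## Problem sizes

The bundled analyses are desk-scale by construction: literature fragment
tables of 5–7 peaks, synthetic datasets of tens of spectra (all-pairs
networking is quadratic but trivially fast at this size), recovery suites
of 100–200 trials, and screening simulations of ~2,000 wells. These sizes
give the recovery rates stable second-decimal precision while keeping the
full test suite under a minute.
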