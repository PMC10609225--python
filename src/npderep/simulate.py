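"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* **Glycoside MS/MS spectra** — an aglycone carrying two trisaccharide
  chains (innermost amino sugar rhodosamine, outer sugars rhodinose or
  2-deoxy-L-fucose) fragments by peeling each chain outermost-first;
  both chain orders are emitted, fragment m/z gets Gaussian jitter,
  intensities decay geometrically down the ladder, an [M+2H]2+
  companion appears with probability 0.5, and uniform noise peaks are
  added below twice the weakest true peak.
* **Analog families** — a parent compound plus analogs differing by a
  small mass transform (±O, ±H2, ...) applied to the aglycone, so the
  whole family shares its fragment-ladder topology and links up under
  the modified cosine.
* **Plates** — OD600 growth with control delta-OD ~ Normal(0.45, 0.03)
  truncated at zero and test delta-OD = control-draw x (1 - effect)
  + Normal(0, 0.01).

The intensity model is invented (real intensity patterns are compound-
and instrument-specific); ladder detection must not depend on it, and
``randomize_intensities`` exists to prove that in tests. Every output is
deterministic under a fixed seed and every expected label is recomputable
from the returned truth records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotate import DeltaTransform
from .bioassay import N_COLS, N_ROWS, PlateLayout
from .constants import PROTON_MASS
from .ladder import DEOXYFUCOSE, RHODINOSE, RHODOSAMINE, SugarResidue
from .spectra_io import MsmsSpectrum, make_spectrum

OUTER_SUGARS: tuple[SugarResidue, ...] = (RHODINOSE, DEOXYFUCOSE)
INNER_SUGAR: SugarResidue = RHODOSAMINE

DEFAULT_TRANSFORM_SET: tuple[DeltaTransform, ...] = (
    DeltaTransform("O", 15.9949),
    DeltaTransform("H2", 2.0157),
    DeltaTransform("H2O", 18.0106),
    DeltaTransform("CH2", 14.0157),
)


@dataclass(frozen=True)
class SimSpec:
    seed: int = 0
    n_families: int = 5
    analogs_per_family: int = 4
    aglycone_mass_range: tuple[float, float] = (350.0, 600.0)
    chain_lengths: tuple[int, ...] = (3, 3)
    mz_sigma: float = 0.01
    n_noise_peaks: int = 20
    noise_mz_range: tuple[float, float] | None = None  # default (100, precursor)
    transform_set: tuple[DeltaTransform, ...] = DEFAULT_TRANSFORM_SET
    intensity_decay: float = 0.7
    companion_prob: float = 0.5
    randomize_intensities: bool = False

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.analogs_per_family < 0 or self.n_noise_peaks < 0:
            raise ValueError("counts must be >= 0")
        if self.mz_sigma < 0:
            raise ValueError("mz_sigma must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    spectrum_id: str
    family: int
    aglycone_mass: float
    chains: tuple[tuple[str, ...], ...]  # residue names, outermost first
    precursor_mz: float
    applied_transforms: tuple[tuple[str, float], ...] = ()  # (name, signed delta)
    has_companion: bool = False

    @property
    def loss_orders(self) -> tuple[tuple[str, ...], ...]:
        """The residue-loss sequences of the emitted chain peel orders."""
        orders = []
        for first in range(len(self.chains)):
            seq: list[str] = []
            for k in list(range(first, len(self.chains))) + list(range(first)):
                seq.extend(self.chains[k])
            orders.append(tuple(seq))
        return tuple(orders)


_RESIDUES = {r.name: r for r in (RHODINOSE, DEOXYFUCOSE, RHODOSAMINE)}


def _sample_chain(length: int, rng: np.random.Generator) -> tuple[str, ...]:
    if length == 0:
        return ()
    outers = rng.choice([s.name for s in OUTER_SUGARS], size=length - 1).tolist()
    return tuple(outers + [INNER_SUGAR.name])


def simulate_glycoside_spectrum(
    spec: SimSpec,
    rng: np.random.Generator,
    spectrum_id: str = "sim_0",
    family: int = 0,
    aglycone_mass: float | None = None,
    chains: tuple[tuple[str, ...], ...] | None = None,
) -> tuple[MsmsSpectrum, SimTruth]:
    """One glycosylated-polyketide MS/MS spectrum plus its ground truth."""
    if aglycone_mass is None:
        aglycone_mass = float(rng.uniform(*spec.aglycone_mass_range))
    if chains is None:
        chains = tuple(_sample_chain(n, rng) for n in spec.chain_lengths)
    residue_mass = sum(_RESIDUES[name].exact_mass for chain in chains for name in chain)
    precursor = aglycone_mass + residue_mass + PROTON_MASS

    mzs: list[float] = [precursor + float(rng.normal(0, spec.mz_sigma))]
    intens: list[float] = [1.0]
    truth = SimTruth(spectrum_id, family, aglycone_mass, chains, precursor)
    for order in truth.loss_orders:
        cum = 0.0
        for depth, name in enumerate(order, start=1):
            cum += _RESIDUES[name].exact_mass
            mzs.append(precursor - cum + float(rng.normal(0, spec.mz_sigma)))
            intens.append(spec.intensity_decay ** depth)
    if rng.uniform() < spec.companion_prob:
        mzs.append((precursor + PROTON_MASS) / 2.0 + float(rng.normal(0, spec.mz_sigma)))
        intens.append(1.0)
        truth = replace(truth, has_companion=True)
    if spec.randomize_intensities:
        intens = rng.uniform(0.1, 1.0, size=len(intens)).tolist()
    if spec.n_noise_peaks:
        lo, hi = spec.noise_mz_range or (100.0, precursor)
        weakest = min(intens)
        mzs.extend(rng.uniform(lo, hi, size=spec.n_noise_peaks).tolist())
        intens.extend(rng.uniform(0.0, 2.0 * weakest, size=spec.n_noise_peaks).tolist())
    spectrum = make_spectrum(spectrum_id, precursor, mzs, intens, source="simulated")
    return spectrum, truth


def simulate_family(
    spec: SimSpec,
    rng: np.random.Generator,
    family: int = 0,
) -> list[tuple[MsmsSpectrum, SimTruth]]:
    """A parent compound plus analogs generated by random transforms.

    Analogs share the parent's sugar chains (hence its ladder topology);
    each applies one transform from ``transform_set`` with a random sign
    to the aglycone, keeping it positive.
    """
    aglycone = float(rng.uniform(*spec.aglycone_mass_range))
    chains = tuple(_sample_chain(n, rng) for n in spec.chain_lengths)
    out = [
        simulate_glycoside_spectrum(
            spec, rng, spectrum_id=f"f{family}_parent", family=family,
            aglycone_mass=aglycone, chains=chains,
        )
    ]
    for j in range(spec.analogs_per_family):
        t = spec.transform_set[int(rng.integers(len(spec.transform_set)))]
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        delta = sign * t.delta_mass
        if aglycone + delta <= 0:
            delta = abs(delta)
        s, tr = simulate_glycoside_spectrum(
            spec, rng, spectrum_id=f"f{family}_analog{j}", family=family,
            aglycone_mass=aglycone + delta, chains=chains,
        )
        out.append((s, replace(tr, applied_transforms=((t.name, delta),))))
    return out


def simulate_dataset(spec: SimSpec) -> tuple[list[MsmsSpectrum], list[SimTruth]]:
    """``n_families`` analog families under the seed in ``spec``."""
    rng = np.random.default_rng(spec.seed)
    spectra: list[MsmsSpectrum] = []
    truths: list[SimTruth] = []
    for fam in range(spec.n_families):
        for s, t in simulate_family(spec, rng, family=fam):
            spectra.append(s)
            truths.append(t)
    return spectra, truths


def random_spectrum(rng: np.random.Generator, spectrum_id: str = "rand",
                    n_peaks: int = 25) -> MsmsSpectrum:
    """An unrelated random spectrum (uniform peaks, no ladder structure)."""
    precursor = float(rng.uniform(400.0, 1200.0))
    mzs = rng.uniform(100.0, precursor, size=n_peaks)
    intens = rng.uniform(0.05, 1.0, size=n_peaks)
    return make_spectrum(spectrum_id, precursor, mzs, intens, source="simulated")


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

EffectModel = Callable[[str, str, str], float]


def simulate_plate(
    n_strains: int,
    n_media: int,
    n_pathogens: int,
    effect_model: EffectModel,
    rng: np.random.Generator,
    n_replicates: int = 3,
    control_delta: tuple[float, float] = (0.45, 0.03),
    well_noise: float = 0.01,
    baseline_od: float = 0.05,
    positive_effect: float = 0.98,
) -> tuple[pd.DataFrame, pd.DataFrame, PlateLayout]:
    """Triplicate 96-well screens with known per-well effects.

    Returns (readings, truth, layout): long-format readings with columns
    (plate_id, replicate, pathogen, row, col, od_t0, od_t24), the truth
    table of true inhibition fractions per (strain, medium, pathogen),
    and the shared plate layout. One plate per pathogen: the strain x
    medium grid must fit the 80 test wells of a plate.
    """
    strains = [f"strain_{i + 1}" for i in range(n_strains)]
    media = [f"FM{j + 1}" for j in range(n_media)]
    pathogens = [f"pathogen_{k + 1}" for k in range(n_pathogens)]
    combos = [(s, m) for s in strains for m in media]
    test_wells = [(r, c) for r in range(2, N_ROWS) for c in range(1, N_COLS + 1)]
    per_plate = len(test_wells)
    if len(combos) > per_plate:
        raise ValueError(f"strain x medium grid ({len(combos)}) exceeds the "
                         f"{per_plate} test wells of one plate")

    def draw_control() -> float:
        while True:
            d = rng.normal(*control_delta)
            if d >= 0:
                return float(d)

    samples = {test_wells[i]: combos[i % len(combos)] for i in range(len(test_wells))}
    layout = PlateLayout.default(samples)
    rows = []
    truth_rows = []
    for pathogen in pathogens:
        for rep in range(1, n_replicates + 1):
            plate_id = f"{pathogen}_r{rep}"
            for (row, col), role in sorted(layout.roles.items()):
                t0 = baseline_od
                if role == "sterility":
                    delta = abs(float(rng.normal(0.0, 0.002)))
                elif role == "negative":
                    delta = draw_control()
                else:
                    if role == "test":
                        strain, medium = layout.samples[(row, col)]
                        effect = effect_model(strain, medium, pathogen)
                    else:
                        effect = positive_effect
                    delta = draw_control() * (1.0 - effect) + float(rng.normal(0.0, well_noise))
                rows.append({"plate_id": plate_id, "replicate": rep,
                             "pathogen": pathogen, "row": row, "col": col,
                             "od_t0": t0, "od_t24": max(t0 + delta, 0.0)})
        for s, m in combos:
            truth_rows.append({"strain": s, "medium": m, "pathogen": pathogen,
                               "effect": effect_model(s, m, pathogen)})
    readings = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return readings, truth, layout
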