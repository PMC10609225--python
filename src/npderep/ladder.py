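"""Deoxysugar neutral-loss ladder detection.

Glycosylated aromatic polyketides (anthracyclines such as the cosmomycins,
angucyclines such as kidamycin) fragment under collision-induced
dissociation by sequentially shedding the sugars of their saccharide
chains: the outermost rhodinose first (-114), then 2-deoxy-L-fucose
(-130), and last the innermost amino sugar rhodosamine (-157). The chain
of these neutral losses — the ladder — is a fingerprint of the glycan
composition and the core dereplication signal of this package.

Two matching modes exist because literature fragment tables print masses
to one decimal against integer nominal losses, while measured spectra
support monoisotopic matching: ``nominal`` compares observed deltas to
integer residue masses (typical tolerance 0.5 Da, occasionally wider for
inconsistently rounded literature values), ``exact`` compares against
monoisotopic residue masses (tolerance of order 0.01-0.03 Da).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import MONOISOTOPIC_MASS, PROTON_MASS
from .spectra_io import MsmsSpectrum

_H2 = 2 * MONOISOTOPIC_MASS["H"]


def formula_mass(formula: dict[str, int]) -> float:
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class SugarResidue:
    """A glycosidic-loss residue (the neutral lost on cleavage)."""

    name: str
    residue_formula: str
    exact_mass: float
    nominal_mass: int

    def __post_init__(self) -> None:
        if self.exact_mass <= 0:
            raise ValueError("exact_mass must be > 0")
        if abs(self.exact_mass - self.nominal_mass) > 0.5:
            raise ValueError(
                f"{self.name}: exact mass {self.exact_mass} too far from nominal {self.nominal_mass}"
            )

    def mass(self, mode: str) -> float:
        return float(self.nominal_mass) if mode == "nominal" else self.exact_mass


# residue masses computed from the element table; literature prints the
# nominal -114 / -130 / -157 losses
RHODINOSE = SugarResidue("rho", "C6H10O2", formula_mass({"C": 6, "H": 10, "O": 2}), 114)
DEOXYFUCOSE = SugarResidue("defuc", "C6H10O3", formula_mass({"C": 6, "H": 10, "O": 3}), 130)
RHODOSAMINE = SugarResidue("RhN", "C8H15NO2", formula_mass({"C": 8, "H": 15, "N": 1, "O": 2}), 157)


@dataclass(frozen=True)
class LossLibrary:
    """The set of sugar residues a ladder step may correspond to."""

    residues: tuple[SugarResidue, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.residues]
        if len(set(names)) != len(names):
            raise ValueError("residue names must be unique")

    @classmethod
    def default(cls, include_dehydro: bool = False) -> "LossLibrary":
        base = [RHODINOSE, DEOXYFUCOSE, RHODOSAMINE]
        if include_dehydro:
            base += [
                SugarResidue(r.name + "-H2", r.residue_formula + "-H2",
                             r.exact_mass - _H2, r.nominal_mass - 2)
                for r in (RHODINOSE, DEOXYFUCOSE, RHODOSAMINE)
            ]
        return cls(tuple(base))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LossLibrary":
        residues = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, formula, exact, nominal = line.split("\t")
            residues.append(SugarResidue(name, formula, float(exact), int(nominal)))
        return cls(tuple(residues))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["name\tformula\texact_mass\tnominal_mass"]
        lines += [f"{r.name}\t{r.residue_formula}\t{r.exact_mass:.6f}\t{r.nominal_mass}"
                  for r in self.residues]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class LadderStep:
    from_mz: float
    to_mz: float
    loss_name: str
    observed_delta: float
    error: float  # observed_delta - library mass in the active mode


@dataclass(frozen=True)
class Ladder:
    spectrum_id: str
    start_mz: float
    steps: tuple[LadderStep, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def terminal_mz(self) -> float:
        return self.steps[-1].to_mz if self.steps else self.start_mz

    @property
    def losses(self) -> tuple[str, ...]:
        return tuple(s.loss_name for s in self.steps)

    @property
    def nominal_losses(self) -> tuple[int, ...]:
        return tuple(int(round(s.observed_delta)) for s in self.steps)

    @property
    def total_error(self) -> float:
        return float(sum(abs(s.error) for s in self.steps))


def detect_ladders(
    s: MsmsSpectrum,
    lib: LossLibrary | None = None,
    tol: float = 0.5,
    mode: Literal["nominal", "exact"] = "nominal",
) -> list[Ladder]:
    """Depth-first search for sugar neutral-loss ladders.

    The search roots at the precursor m/z (or the most intense peak within
    ``tol`` of it, if present). At each level every residue of ``lib`` is
    tried against every peak within ``tol`` of ``current - residue_mass``
    (closest first), each peak usable once per path. Every maximal
    root-to-leaf path with at least one step becomes a :class:`Ladder`;
    results are deduplicated on the step sequence and sorted by
    (n_steps descending, total |error| ascending).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    lib = lib or LossLibrary.default()
    mz = s.mz
    if mz.size == 0:
        return []
    root = s.precursor_mz
    near = np.abs(mz - root) <= tol
    if np.any(near):
        idx = np.flatnonzero(near)
        root = float(mz[idx[np.argmax(s.intensity[near])]])

    ladders: dict[tuple, Ladder] = {}

    def _candidates(target: float, used: frozenset[int]) -> list[int]:
        lo = int(np.searchsorted(mz, target - tol, side="left"))
        hi = int(np.searchsorted(mz, target + tol, side="right"))
        ks = [k for k in range(lo, hi) if k not in used and abs(mz[k] - target) <= tol]
        ks.sort(key=lambda k: (abs(mz[k] - target), mz[k]))  # closest first
        return ks

    def _extend(current: float, used: frozenset[int], path: tuple[LadderStep, ...]) -> None:
        extended = False
        for res in lib.residues:
            target = current - res.mass(mode)
            if target <= 0:
                continue
            for k in _candidates(target, used):
                extended = True
                to_mz = float(mz[k])
                delta = current - to_mz
                step = LadderStep(current, to_mz, res.name, delta, delta - res.mass(mode))
                _extend(to_mz, used | {k}, path + (step,))
        if not extended and path:
            key = tuple((st.loss_name, st.to_mz) for st in path)
            ladders.setdefault(key, Ladder(s.id, root, path))

    _extend(root, frozenset(), ())
    out = sorted(ladders.values(), key=lambda l: (-l.n_steps, l.total_error, l.losses))
    return out


def best_ladder(ladders: Sequence[Ladder]) -> Ladder | None:
    """First ladder after the deterministic sort; ``None`` on empty input."""
    return ladders[0] if ladders else None


def charge_companion_mz(mh: float) -> float:
    """[M+2H]2+ m/z for a compound whose [M+H]+ is ``mh``."""
    if mh <= PROTON_MASS:
        raise ValueError(f"[M+H]+ m/z must exceed the proton mass, got {mh}")
    return (mh + PROTON_MASS) / 2.0


def find_charge_companions(s: MsmsSpectrum, tol: float = 0.5) -> list[tuple[float, float]]:
    """All peak pairs (p, q) where q sits at the [M+2H]2+ companion m/z of p."""
    out = []
    for p in s.mz:
        if p <= PROTON_MASS:
            continue
        target = charge_companion_mz(float(p))
        for q in s.mz[np.abs(s.mz - target) <= tol]:
            out.append((float(p), float(q)))
    return out


def glycan_composition(ladder: Ladder) -> Counter:
    """Multiset of residue names along the ladder (order kept in the ladder)."""
    return Counter(step.loss_name for step in ladder.steps)


def ladder_report(ladders: Iterable[Ladder], path: str | Path) -> None:
    lines = ["spectrum_id\tstart_mz\tn_steps\tlosses\tnominal_losses\tterminal_mz\ttotal_abs_error"]
    for l in ladders:
        lines.append(
            f"{l.spectrum_id}\t{l.start_mz:.4f}\t{l.n_steps}\t"
            f"{','.join(l.losses)}\t{','.join(map(str, l.nominal_losses))}\t"
            f"{l.terminal_mz:.4f}\t{l.total_error:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
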