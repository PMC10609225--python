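"""Accurate-mass ion arithmetic and elemental-formula enumeration.

Everything here works on positive even-electron cations written with
their charge-carrying protons included (the [M+H]+ convention of
natural-product literature): ``C60H87N2O22`` with charge 1 *is* the
protonated molecule. Theoretical m/z subtracts the electron mass, the
true cation mass; the 0.55 mDa difference is below typical reporting
precision but documented.

Formula enumeration scans a bounded CHNOS lattice, solving the hydrogen
count analytically per (C, N, O, S) combination, and filters by
rings-plus-double-bond equivalents (RDBE) and an H/C plausibility window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS

ELEMENTS = ("C", "H", "N", "O", "S")
_MASS = np.array([MONOISOTOPIC_MASS[e] for e in ELEMENTS])

DEFAULT_BOUNDS: dict[str, int] = {"C": 70, "H": 130, "N": 6, "O": 26, "S": 2}
DEFAULT_RDBE_RANGE: tuple[float, float] = (0.0, 40.0)
DEFAULT_HC_RANGE: tuple[float, float] = (0.2, 3.2)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class IonFormula:
    """Elemental composition of a positive ion, protons included.

    ``counts`` maps element symbol to a non-negative integer; at least one
    atom is required and the charge is a positive integer.
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1 (positive ions only)")
        if sum(n for _, n in self.counts) < 1:
            raise ValueError("formula must contain at least one atom")
        for el, n in self.counts:
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")

    @classmethod
    def from_counts(cls, charge: int = 1, **counts: int) -> "IonFormula":
        return cls(tuple((el, counts.get(el, 0)) for el in ELEMENTS if counts.get(el, 0)), charge)

    @classmethod
    def parse(cls, text: str, charge: int = 1) -> "IonFormula":
        """Parse e.g. ``"C60H87N2O22"``; an omitted count means 1."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls.from_counts(charge=charge, **counts)

    def count(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def hill_string(self) -> str:
        d = dict(self.counts)
        order = ["C", "H"] + sorted(e for e in d if e not in ("C", "H"))
        return "".join(f"{e}{d[e] if d[e] != 1 else ''}" for e in order if d.get(e, 0))

    def __str__(self) -> str:
        plus = "+" if self.charge == 1 else f"{self.charge}+"
        return f"[{self.hill_string()}]{plus}"


def theoretical_mz(f: IonFormula) -> float:
    """m/z of the cation: (sum of atom masses - charge electrons) / charge."""
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts)
    return (mass - f.charge * ELECTRON_MASS) / f.charge


def rdbe(f: IonFormula) -> float:
    """Rings-plus-double-bond equivalents: C - H/2 + N/2 + 1.

    O and S contribute zero; even-electron cations give half-integer
    values because a charge-carrying proton is counted in H.
    """
    return f.count("C") - f.count("H") / 2.0 + f.count("N") / 2.0 + 1.0


@dataclass(frozen=True)
class FormulaCandidate:
    formula: IonFormula
    theo_mz: float
    ppm_error: float
    rdbe: float


def _passes_filters(c: int, h: int, n: int, o: int, s: int,
                    rdbe_range: tuple[float, float],
                    hc_range: tuple[float, float] | None) -> bool:
    r = c - h / 2.0 + n / 2.0 + 1.0
    if not (rdbe_range[0] <= r <= rdbe_range[1]):
        return False
    if hc_range is not None and c > 0:
        ratio = h / c
        if not (hc_range[0] <= ratio <= hc_range[1]):
            return False
    return True


def enumerate_formulas(
    mz: float,
    charge: int = 1,
    ppm_tol: float = 10.0,
    bounds: dict[str, int] | None = None,
    rdbe_range: tuple[float, float] = DEFAULT_RDBE_RANGE,
    hc_range: tuple[float, float] | None = DEFAULT_HC_RANGE,
) -> list[FormulaCandidate]:
    """All CHNOS compositions whose cation m/z lies within ``ppm_tol`` of
    ``mz``, sorted by |ppm error| (ties by Hill string).

    The scan is exhaustive over the bounded lattice: for each (C, N, O, S)
    the feasible hydrogen counts are solved from the mass window directly,
    which is equivalent to — and tested against — an unpruned brute force.
    """
    if mz <= 0:
        raise ValueError("mz must be > 0")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    target = mz * charge + charge * ELECTRON_MASS  # neutral-atom mass sum
    tol = mz * ppm_tol * 1e-6 * charge
    mh = MONOISOTOPIC_MASS["H"]
    out: list[FormulaCandidate] = []
    for s in range(bounds.get("S", 0) + 1):
        ms = s * MONOISOTOPIC_MASS["S"]
        if ms > target + tol:
            break
        for n in range(bounds.get("N", 0) + 1):
            mn = ms + n * MONOISOTOPIC_MASS["N"]
            if mn > target + tol:
                break
            for o in range(bounds.get("O", 0) + 1):
                mo = mn + o * MONOISOTOPIC_MASS["O"]
                if mo > target + tol:
                    break
                for c in range(bounds.get("C", 0) + 1):
                    rem = target - mo - c * MONOISOTOPIC_MASS["C"]
                    if rem < -tol:
                        break
                    h_lo = max(0, int(np.ceil((rem - tol) / mh)))
                    h_hi = min(bounds.get("H", 0), int(np.floor((rem + tol) / mh)))
                    for h in range(h_lo, h_hi + 1):
                        if c + h + n + o + s < 1:
                            continue
                        if not _passes_filters(c, h, n, o, s, rdbe_range, hc_range):
                            continue
                        f = IonFormula.from_counts(charge=charge, C=c, H=h, N=n, O=o, S=s)
                        theo = theoretical_mz(f)
                        ppm = (theo - mz) / mz * 1e6
                        if abs(ppm) <= ppm_tol:
                            out.append(FormulaCandidate(f, theo, ppm, rdbe(f)))
    out.sort(key=lambda cand: (abs(cand.ppm_error), cand.formula.hill_string()))
    return out


def candidates_tsv(cands: Sequence[FormulaCandidate]) -> str:
    lines = ["rank\tformula\ttheo_mz\tppm_error\trdbe"]
    for rank, c in enumerate(cands, start=1):
        lines.append(f"{rank}\t{c.formula.hill_string()}\t{c.theo_mz:.6f}\t"
                     f"{c.ppm_error:.3f}\t{c.rdbe:.1f}")
    return "\n".join(lines) + "\n"
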