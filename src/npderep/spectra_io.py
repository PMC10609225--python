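"""Reading, validating and writing centroided MS/MS spectra.

Two formats are supported: Mascot Generic Format (MGF), the de-facto
interchange format for molecular-networking inputs, and a minimal
tab-separated peak-list dialect (``#precursor=`` / ``#id=`` headers plus
two numeric columns) used to encode literature fragment tables as
plain-text fixtures.

All spectra are canonicalized on construction: peaks sorted by ascending
m/z, peaks closer than 1e-6 Th merged by intensity sum, non-positive m/z
rejected. Intensities are optional in the ladder logic downstream; a
missing intensity defaults to 1.0.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

Peak = namedtuple("Peak", ["mz", "intensity"])

#: duplicate m/z values within this distance are merged by intensity sum
MERGE_EPS = 1e-6


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum records (names record index and line)."""


@dataclass(frozen=True)
class MsmsSpectrum:
    """One centroided MS/MS scan.

    Parameters
    ----------
    id : unique text identifier (MGF TITLE or running index).
    precursor_mz : precursor ion m/z in Th.
    charge : positive integer precursor charge, default 1.
    mz, intensity : peak arrays, canonicalized (sorted, merged) on init.
    retention_time : minutes, optional.
    source : provenance text (file path, simulation tag, ...).
    """

    id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1
    retention_time: float | None = None
    source: str = ""
    _canonical: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be > 0, got {self.precursor_mz}")
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")
        if not self._canonical:
            mz, inten = _canonicalize(self.mz, self.intensity)
            object.__setattr__(self, "mz", mz)
            object.__setattr__(self, "intensity", inten)
            object.__setattr__(self, "_canonical", True)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def with_peaks(self, mz: Sequence[float], intensity: Sequence[float]) -> "MsmsSpectrum":
        return replace(
            self,
            mz=np.asarray(mz, dtype=float),
            intensity=np.asarray(intensity, dtype=float),
            _canonical=False,
        )

    def __eq__(self, other: object) -> bool:  # arrays break dataclass eq
        if not isinstance(other, MsmsSpectrum):
            return NotImplemented
        return (
            self.id == other.id
            and self.precursor_mz == other.precursor_mz
            and self.charge == other.charge
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )


def _canonicalize(mz: Sequence[float], intensity: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    mz = np.asarray(mz, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if mz.shape != inten.shape:
        raise ValueError("mz and intensity arrays must have equal length")
    if mz.size == 0:
        return mz.copy(), inten.copy()
    if np.any(mz <= 0):
        raise ValueError("peak m/z values must be > 0")
    if np.any(inten < 0):
        raise ValueError("peak intensities must be >= 0")
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # merge runs of peaks closer than MERGE_EPS
    keep_mz: list[float] = [mz[0]]
    keep_in: list[float] = [inten[0]]
    for m, i in zip(mz[1:], inten[1:]):
        if m - keep_mz[-1] <= MERGE_EPS:
            keep_in[-1] += i
        else:
            keep_mz.append(m)
            keep_in.append(i)
    return np.asarray(keep_mz), np.asarray(keep_in)


def make_spectrum(
    id: str,
    precursor_mz: float,
    mz: Sequence[float],
    intensity: Sequence[float] | None = None,
    charge: int = 1,
    **kw,
) -> MsmsSpectrum:
    """Convenience constructor; missing intensities default to 1.0."""
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return MsmsSpectrum(id=id, precursor_mz=float(precursor_mz), mz=mz,
                        intensity=np.asarray(intensity, dtype=float),
                        charge=charge, **kw)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read an MGF file into canonical spectra.

    Accepts ``PEPMASS=<mz> [<intensity>]`` and ``CHARGE=<n>+``; a missing
    CHARGE defaults to 1 and TITLE (or the running record index) becomes
    the spectrum id. Unknown headers are ignored with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[MsmsSpectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        index = 0
        while True:
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # non-numeric peak line etc.
                raise SpectrumFormatError(
                    f"malformed MGF record #{index} in {path.name}: {exc}"
                ) from exc
            params = entry.get("params", {})
            if "pepmass" not in params:
                raise SpectrumFormatError(
                    f"malformed MGF record #{index} in {path.name}: missing PEPMASS"
                )
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = 1
            if params.get("charge"):
                charge = abs(int(params["charge"][0]))
            title = str(params.get("title", "") or f"scan_{index}")
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else None
            known = {"pepmass", "charge", "title", "rtinseconds"}
            for key in params:
                if key not in known:
                    logger.warning("ignoring MGF header %s in record #%d", key.upper(), index)
            spectra.append(
                make_spectrum(
                    id=title,
                    precursor_mz=precursor,
                    mz=entry.get("m/z array", np.empty(0)),
                    intensity=entry.get("intensity array", np.empty(0)),
                    charge=charge,
                    retention_time=rt_min,
                    source=str(path),
                )
            )
            index += 1
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    """Write spectra to MGF; ``read_mgf(write_mgf(x))`` round-trips
    precursor m/z, charge and peaks to 1e-6."""
    records = []
    for s in spectra:
        params = {"title": s.id, "pepmass": s.precursor_mz, "charge": f"{s.charge}+"}
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time * 60.0
        records.append({
            "params": params,
            "m/z array": s.mz,
            "intensity array": s.intensity,
        })
    _mgf.write(records, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# TSV peak-list dialect
# ---------------------------------------------------------------------------

def read_peaklist_tsv(path: str | Path) -> MsmsSpectrum:
    """Read the two-column (mz, intensity) dialect with ``#precursor=`` /
    ``#id=`` header lines; intensity column is optional (defaults 1.0)."""
    path = Path(path)
    precursor: float | None = None
    spec_id: str | None = None
    charge = 1
    mzs: list[float] = []
    intens: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            key = key.strip().lower()
            if key == "precursor":
                precursor = float(value)
            elif key == "id":
                spec_id = value.strip()
            elif key == "charge":
                charge = int(value)
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            mzs.append(float(fields[0]))
            intens.append(float(fields[1]) if len(fields) > 1 else 1.0)
        except ValueError as exc:
            raise SpectrumFormatError(f"{path.name}:{lineno}: non-numeric peak line {raw!r}") from exc
    if precursor is None:
        raise SpectrumFormatError(f"{path.name}: missing '#precursor=' header")
    return make_spectrum(
        id=spec_id or path.stem,
        precursor_mz=precursor,
        mz=mzs,
        intensity=intens,
        charge=charge,
        source=str(path),
    )


def write_peaklist_tsv(spectrum: MsmsSpectrum, path: str | Path) -> None:
    lines = [f"#id={spectrum.id}", f"#precursor={float(spectrum.precursor_mz)!r}",
             f"#charge={spectrum.charge}"]
    lines += [f"{float(m)!r}\t{float(i)!r}" for m, i in zip(spectrum.mz, spectrum.intensity)]
    Path(path).write_text("\n".join(lines) + "\n")
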