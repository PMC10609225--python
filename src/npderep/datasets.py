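"""Bundled reference data.

Small plain-text fixtures shipped with the package: the literature MS2
fragment tables of cosmomycin D, cosmomycin C and the cosmomycin C
structural isomer ("compound 12"), the deoxysugar loss library, the
seed compound library (cosmomycins, kidamycins and their reported
derivatives with printed [M+H]+ masses), and the analog transform table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .annotate import CompoundRecord, DeltaTransform, load_seed_library, load_transforms
from .ladder import LossLibrary
from .spectra_io import MsmsSpectrum, read_peaklist_tsv


def _data_path(name: str) -> Path:
    return Path(resources.files("npderep") / "data" / name)


def cosmomycin_d_spectrum() -> MsmsSpectrum:
    """Printed MS2 fragment table of cosmomycin D ([M+H]+ 1189.6)."""
    return read_peaklist_tsv(_data_path("cosmomycinD.tsv"))


def cosmomycin_c_spectrum() -> MsmsSpectrum:
    """Printed MS2 fragment table of cosmomycin C (products of 1173.3)."""
    return read_peaklist_tsv(_data_path("cosmomycinC.tsv"))


def compound12_spectrum() -> MsmsSpectrum:
    """Printed MS2 fragment table of the cosmomycin C isomer (precursor 1173.6)."""
    return read_peaklist_tsv(_data_path("compound12.tsv"))


def default_loss_library() -> LossLibrary:
    return LossLibrary.from_tsv(_data_path("loss_library.tsv"))


def seed_compound_library() -> list[CompoundRecord]:
    return load_seed_library(_data_path("seed_library.tsv"))


def transform_library() -> list[DeltaTransform]:
    return load_transforms(_data_path("transforms.tsv"))
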