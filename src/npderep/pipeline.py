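"""End-to-end orchestration: spectra -> network -> ladders -> formulas ->
seed matching -> analog propagation -> joined report, with a JSON run
manifest that records every parameter and count so a rerun with the same
configuration reproduces the outputs byte for byte."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import datasets
from .annotate import (
    annotation_report,
    export_annotated_graphml,
    load_seed_library,
    load_transforms,
    match_seeds,
    propagate,
)
from .formula import enumerate_formulas
from .ladder import LossLibrary, best_ladder, detect_ladders, ladder_report
from .network import NetworkParams, build_network, export_edges_tsv, export_nodes_tsv
from .spectra_io import MsmsSpectrum, read_mgf, read_peaklist_tsv

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or missing input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    spectra_dir: str = ""
    out_dir: str = "npderep_out"
    seed_library: str | None = None  # None -> bundled library
    loss_library: str | None = None
    transform_library: str | None = None
    network: NetworkParams = field(default_factory=NetworkParams)
    ladder_tol: float = 0.5
    ladder_mode: str = "nominal"
    formula_ppm: float = 10.0
    enumerate_node_formulas: bool = False
    propagation_tol: float = 0.01
    max_hops: int = 2
    seed_match_tol: float = 0.02

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except Exception as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        raw.update({k: v for k, v in overrides.items() if v is not None})
        net = raw.pop("network", {})
        try:
            return cls(network=NetworkParams(**net), **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if self.ladder_mode not in ("nominal", "exact"):
            raise ConfigError(f"ladder_mode must be nominal|exact, got {self.ladder_mode!r}")
        for name in ("ladder_tol", "formula_ppm", "propagation_tol", "seed_match_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.max_hops < 1:
            raise ConfigError("max_hops must be >= 1")


def load_spectra_dir(path: str | Path) -> list[MsmsSpectrum]:
    path = Path(path)
    if not path.is_dir():
        raise DataError(f"spectra directory {path} does not exist")
    spectra: list[MsmsSpectrum] = []
    for f in sorted(path.glob("*.mgf")):
        spectra.extend(read_mgf(f))
    for f in sorted(path.glob("*.tsv")):
        spectra.append(read_peaklist_tsv(f))
    return spectra


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write the report bundle.

    Returns the manifest dict. An empty spectra directory is a clean
    no-op (manifest records zero inputs).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spectra = load_spectra_dir(config.spectra_dir)
    manifest: dict = {
        "parameters": {
            "network": asdict(config.network),
            "ladder_tol": config.ladder_tol,
            "ladder_mode": config.ladder_mode,
            "formula_ppm": config.formula_ppm,
            "propagation_tol": config.propagation_tol,
            "max_hops": config.max_hops,
            "seed_match_tol": config.seed_match_tol,
        },
        "n_spectra": len(spectra),
    }
    if not spectra:
        logger.warning("no input spectra found in %s", config.spectra_dir)
        manifest.update(n_nodes=0, n_edges=0, n_annotations=0)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest

    try:
        net = build_network(spectra, config.network)
        export_edges_tsv(net, out / "edges.tsv")
        export_nodes_tsv(net, out / "nodes.tsv")
    except Exception as exc:
        raise DataError(f"stage network failed: {exc}") from exc

    loss_lib = (LossLibrary.from_tsv(config.loss_library) if config.loss_library
                else datasets.default_loss_library())
    by_id = {s.id: s for s in spectra}
    ladders = {}
    for node in sorted(net.nodes):
        found = detect_ladders(by_id[node], loss_lib, tol=config.ladder_tol,
                               mode=config.ladder_mode)  # type: ignore[arg-type]
        best = best_ladder(found)
        if best is not None:
            ladders[node] = best
    ladder_report(ladders.values(), out / "ladders.tsv")

    formulas = {}
    if config.enumerate_node_formulas:
        for node in sorted(net.nodes):
            formulas[node] = enumerate_formulas(net.nodes[node]["precursor_mz"],
                                                ppm_tol=config.formula_ppm)

    seed_lib = (load_seed_library(config.seed_library) if config.seed_library
                else datasets.seed_compound_library())
    transforms = (load_transforms(config.transform_library) if config.transform_library
                  else datasets.transform_library())
    seeds = match_seeds(net, seed_lib, tol=config.seed_match_tol)
    annotations = propagate(net, seeds, transforms, tol=config.propagation_tol,
                            max_hops=config.max_hops)
    annotation_report(net, annotations, ladders, formulas, out / "annotations.tsv")
    export_annotated_graphml(net, annotations, out / "network.graphml")

    manifest.update(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        n_ladders=len(ladders),
        n_seed_matches=sum(1 for a in annotations if a.evidence == "seed_match"),
        n_annotations=len(annotations),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
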