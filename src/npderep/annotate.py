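"""Seed-library matching and network-propagated analog annotation.

Known compounds (a seed library of name / [M+H]+ m/z pairs) are matched
to network nodes by precursor mass; labels then propagate breadth-first
along network edges when the parent-mass difference of an edge matches a
small chemical transform — oxygenation (±O, 15.9949), saturation (±H2,
2.0157), hydration (±H2O), methylenation (±CH2), acetylation (±C2H2O),
or gain/loss of a whole deoxysugar residue. This mirrors the manual
"mass-difference" reasoning used to identify putative analogs of an
annotated compound inside a molecular-network cluster.

Propagation uses a tighter tolerance (default 0.01 Da) than networking
(0.02 Da) because neighbouring transform masses must stay discriminable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .formula import IonFormula
from .ladder import DEOXYFUCOSE, RHODINOSE, RHODOSAMINE, Ladder, glycan_composition


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    ion_mz: float  # [M+H]+
    ion_formula: str | None = None
    compound_class: str = "other"  # anthracycline | angucycline | other

    def __post_init__(self) -> None:
        if self.ion_mz <= 0:
            raise ValueError("ion_mz must be > 0")
        if self.ion_formula:
            IonFormula.parse(self.ion_formula)  # validate


@dataclass(frozen=True)
class DeltaTransform:
    """A mass difference that relates structural analogs (applies both ways)."""

    name: str
    delta_mass: float

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValueError("store positive delta_mass; it applies in both directions")

    @property
    def nominal(self) -> int:
        return int(round(self.delta_mass))


DEFAULT_TRANSFORMS: tuple[DeltaTransform, ...] = (
    DeltaTransform("O", 15.9949),
    DeltaTransform("H2", 2.0157),
    DeltaTransform("H2O", 18.0106),
    DeltaTransform("CH2", 14.0157),
    DeltaTransform("acetyl", 42.0106),
    DeltaTransform("rho", RHODINOSE.exact_mass),
    DeltaTransform("defuc", DEOXYFUCOSE.exact_mass),
    DeltaTransform("RhN", RHODOSAMINE.exact_mass),
)


@dataclass(frozen=True)
class Annotation:
    node_id: str
    label: str
    evidence: str  # seed_match | propagated
    hops: int
    cumulative_delta: float
    seed: str
    transform_chain: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.hops == 0) != (self.evidence == "seed_match"):
            raise ValueError("hops == 0 iff evidence == seed_match")


def load_seed_library(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.to_dict("records"):
        formula = row.get("ion_formula")
        if formula is None or pd.isna(formula):
            formula = None
        records.append(CompoundRecord(str(row["name"]), float(row["ion_mz"]), formula,
                                      str(row.get("compound_class", "other"))))
    return records


def load_transforms(path: str | Path) -> list[DeltaTransform]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [DeltaTransform(str(r["name"]), float(r["delta_mass"]))
            for r in df.to_dict("records")]


def match_seeds(net: nx.Graph, lib: Sequence[CompoundRecord], tol: float = 0.02) -> list[Annotation]:
    """Annotate each node with the nearest library compound within ``tol``
    (Da on the precursor m/z); ties break by smaller |delta|, then library order."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    out = []
    for node in sorted(net.nodes):
        prec = net.nodes[node]["precursor_mz"]
        best: CompoundRecord | None = None
        best_d = tol
        for rec in lib:  # stable scan -> library order breaks exact ties
            d = abs(prec - rec.ion_mz)
            if d < best_d or (d == best_d and best is None):
                best, best_d = rec, d
        if best is not None:
            out.append(Annotation(node, best.name, "seed_match", 0, 0.0, best.name))
    return out


def propagate(
    net: nx.Graph,
    seeds: Sequence[Annotation],
    transforms: Sequence[DeltaTransform] = DEFAULT_TRANSFORMS,
    tol: float = 0.01,
    max_hops: int = 2,
    allow_pairs: bool = False,
) -> list[Annotation]:
    """Breadth-first analog propagation from seed-matched nodes.

    An unannotated neighbour is labelled ``analog of <seed> via <chain>``
    when the edge's parent-mass delta matches a single transform (or, with
    ``allow_pairs``, a sum of two) within ``tol``. The shortest-hop
    annotation wins; equal hops resolve by smallest |delta error|.
    Returns seed annotations plus propagated ones.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    candidates = list(_single_and_pair_transforms(transforms, allow_pairs))
    annotated: dict[str, Annotation] = {a.node_id: a for a in seeds}
    frontier = sorted(annotated)
    for hop in range(1, max_hops + 1):
        proposals: dict[str, tuple[float, Annotation]] = {}
        for node in frontier:
            parent = annotated[node]
            for nbr in sorted(net.neighbors(node)):
                if nbr in annotated:
                    continue
                delta = abs(net.nodes[node]["precursor_mz"] - net.nodes[nbr]["precursor_mz"])
                match = _best_transform(delta, candidates, tol)
                if match is None:
                    continue
                names, err = match
                chain = parent.transform_chain + names
                ann = Annotation(
                    nbr,
                    f"analog of {parent.seed} via {'+'.join(chain)}",
                    "propagated",
                    hop,
                    parent.cumulative_delta + delta,
                    parent.seed,
                    chain,
                )
                if nbr not in proposals or err < proposals[nbr][0]:
                    proposals[nbr] = (err, ann)
        if not proposals:
            break
        for nbr, (_, ann) in proposals.items():
            annotated[nbr] = ann
        frontier = sorted(proposals)
    return [annotated[k] for k in sorted(annotated)]


def _single_and_pair_transforms(
    transforms: Sequence[DeltaTransform], allow_pairs: bool
) -> Iterable[tuple[tuple[str, ...], float]]:
    for t in transforms:
        yield (t.name,), t.delta_mass
    if allow_pairs:
        for i, a in enumerate(transforms):
            for b in transforms[i:]:
                yield (a.name, b.name), a.delta_mass + b.delta_mass


def _best_transform(
    delta: float, candidates: Sequence[tuple[tuple[str, ...], float]], tol: float
) -> tuple[tuple[str, ...], float] | None:
    best = None
    best_err = tol
    for names, mass in candidates:
        err = abs(delta - mass)
        if err < best_err or (err == best_err and best is None):
            best, best_err = names, err
    return (best, best_err) if best is not None else None


def annotation_report(
    net: nx.Graph,
    annotations: Sequence[Annotation],
    ladders: Mapping[str, Ladder] | None = None,
    formulas: Mapping[str, Sequence] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Joined per-node table: precursor, label, evidence, best ladder
    composition and top formula candidates; one row per reported node."""
    ladders = ladders or {}
    formulas = formulas or {}
    by_node = {a.node_id: a for a in annotations}
    rows = []
    for node in sorted(net.nodes):
        ann = by_node.get(node)
        lad = ladders.get(node)
        comp = ""
        if lad is not None and lad.n_steps:
            comp = ",".join(f"{k}:{v}" for k, v in sorted(glycan_composition(lad).items()))
        cands = formulas.get(node, [])
        top = ";".join(c.formula.hill_string() for c in list(cands)[:3])
        rows.append({
            "node_id": node,
            "precursor_mz": round(net.nodes[node]["precursor_mz"], 4),
            "label": ann.label if ann else "",
            "evidence": ann.evidence if ann else "",
            "hops": ann.hops if ann else "",
            "glycan_composition": comp,
            "top_formulas": top,
        })
    df = pd.DataFrame(rows, columns=["node_id", "precursor_mz", "label", "evidence",
                                     "hops", "glycan_composition", "top_formulas"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def export_annotated_graphml(net: nx.Graph, annotations: Sequence[Annotation],
                             path: str | Path) -> None:
    g = net.copy()
    for a in annotations:
        if a.node_id in g:
            g.nodes[a.node_id]["label"] = a.label
            g.nodes[a.node_id]["evidence"] = a.evidence
    nx.write_graphml(g, str(path))
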