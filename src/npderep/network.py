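"""Modified-cosine spectral similarity and molecular-network construction.

The modified cosine allows a fragment in one spectrum to match a fragment
in the other either at the same m/z or offset by the difference of the two
precursor masses, so structural analogs that share a backbone but differ
by one modification still score highly. The network keeps an edge when the
score and matched-peak count pass thresholds, the edge is in the top-K of
both endpoints, and the component it lands in stays below a size cap —
the conventions of GNPS-style networking, implemented natively here with
an exact maximum-weight one-to-one peak matching.

Default parameters: minimum cosine 0.6, parent mass tolerance 0.02 Da,
fragment tolerance 0.02 Da, minimum matched peaks 4, minimum cluster
size 2, top-K edges 10, maximum component size 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra_io import MsmsSpectrum


@dataclass(frozen=True)
class NetworkParams:
    min_cosine: float = 0.6
    parent_mass_tol: float = 0.02
    frag_tol: float = 0.02
    min_matched_peaks: int = 4
    min_cluster_size: int = 2
    top_k_edges: int = 10
    max_component_size: int = 100

    def __post_init__(self) -> None:
        if self.parent_mass_tol <= 0 or self.frag_tol <= 0:
            raise ValueError("tolerances must be > 0")
        for name in ("min_matched_peaks", "min_cluster_size", "top_k_edges",
                     "max_component_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.min_cosine <= 1.0:
            raise ValueError("min_cosine must be in [0, 1]")


@dataclass(frozen=True)
class CosineScore:
    score: float
    n_matched: int


def preprocess_spectrum(
    s: MsmsSpectrum,
    precursor_window: float = 17.0,
    top_k_per_window: int = 6,
    window: float = 50.0,
) -> MsmsSpectrum:
    """Standard networking preprocessing.

    Removes peaks within ``precursor_window`` Da of the precursor, keeps a
    peak only if it ranks among the ``top_k_per_window`` most intense peaks
    inside the ``window``-Da neighbourhood centred on it, and square-root
    transforms the surviving intensities.
    """
    mz, inten = s.mz, s.intensity
    far = np.abs(mz - s.precursor_mz) > precursor_window
    mz, inten = mz[far], inten[far]
    keep = np.ones(mz.size, dtype=bool)
    half = window / 2.0
    for i in range(mz.size):
        lo = np.searchsorted(mz, mz[i] - half, side="left")
        hi = np.searchsorted(mz, mz[i] + half, side="right")
        neigh = inten[lo:hi]
        # rank by (intensity desc, mz asc); peak survives if in top k
        rank = int(np.sum(neigh > inten[i]))
        ties_before = int(np.sum(neigh[: i - lo] == inten[i]))
        keep[i] = rank + ties_before < top_k_per_window
    return s.with_peaks(mz[keep], np.sqrt(inten[keep]))


def _candidate_pairs(a: MsmsSpectrum, b: MsmsSpectrum, frag_tol: float) -> list[tuple[int, int]]:
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i, ma in enumerate(a.mz):
        for j, mb in enumerate(b.mz):
            d = ma - mb
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                pairs.append((i, j))
    return pairs


def modified_cosine(a: MsmsSpectrum, b: MsmsSpectrum, frag_tol: float = 0.02) -> CosineScore:
    """Modified-cosine similarity via exact maximum-weight one-to-one matching.

    A peak pair (i, j) is a candidate if |mzA_i - mzB_j| <= frag_tol or if
    the difference equals the precursor-mass difference within frag_tol.
    The score is the maximum over one-to-one matchings of the sum of
    products of L2-normalized intensities; spectra are expected to be
    preprocessed (sqrt-transformed) already. Zero-intensity spectra score 0.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        return CosineScore(0.0, 0)
    na = float(np.linalg.norm(a.intensity))
    nb = float(np.linalg.norm(b.intensity))
    if na == 0.0 or nb == 0.0:
        return CosineScore(0.0, 0)
    ia = a.intensity / na
    ib = b.intensity / nb
    pairs = _candidate_pairs(a, b, frag_tol)
    if not pairs:
        return CosineScore(0.0, 0)
    rows = sorted({i for i, _ in pairs})
    cols = sorted({j for _, j in pairs})
    rmap = {i: r for r, i in enumerate(rows)}
    cmap = {j: c for c, j in enumerate(cols)}
    weight = np.zeros((len(rows), len(cols)))
    for i, j in pairs:
        w = ia[i] * ib[j]
        if w > weight[rmap[i], cmap[j]]:
            weight[rmap[i], cmap[j]] = w
    ri, ci = linear_sum_assignment(weight, maximize=True)
    candidate = set(pairs)
    score = 0.0
    n_matched = 0
    for r, c in zip(ri, ci):
        if (rows[r], cols[c]) in candidate and weight[r, c] > 0.0:
            score += weight[r, c]
            n_matched += 1
    return CosineScore(min(float(score), 1.0), n_matched)


def build_network(spectra: Sequence[MsmsSpectrum], params: NetworkParams = NetworkParams(),
                  preprocess: bool = True) -> nx.Graph:
    """All-pairs modified cosine, thresholding, mutual top-K edge pruning,
    component-size reduction and small-component removal.

    Returns an undirected :class:`networkx.Graph` whose nodes carry
    ``precursor_mz`` and edges carry ``score``, ``n_matched`` and
    ``delta_parent_mass``. Components smaller than ``min_cluster_size``
    (singletons at the default) are dropped from the reported network.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    prepped = [preprocess_spectrum(s) if preprocess else s for s in spectra]
    g = nx.Graph()
    for s in spectra:
        g.add_node(s.id, precursor_mz=float(s.precursor_mz))
    for i in range(len(prepped)):
        for j in range(i + 1, len(prepped)):
            cs = modified_cosine(prepped[i], prepped[j], params.frag_tol)
            if cs.score >= params.min_cosine and cs.n_matched >= params.min_matched_peaks:
                g.add_edge(
                    spectra[i].id, spectra[j].id,
                    score=round(float(cs.score), 12),
                    n_matched=int(cs.n_matched),
                    delta_parent_mass=float(spectra[i].precursor_mz - spectra[j].precursor_mz),
                )
    _prune_top_k(g, params.top_k_edges)
    _reduce_components(g, params.max_component_size)
    # drop components below the minimum cluster size
    for comp in list(nx.connected_components(g)):
        if len(comp) < params.min_cluster_size:
            g.remove_nodes_from(comp)
    return g


def _edge_sort_key(g: nx.Graph, u, v):
    d = g.edges[u, v]
    return (d["score"], -abs(d["delta_parent_mass"]), tuple(sorted((u, v))))


def _prune_top_k(g: nx.Graph, k: int) -> None:
    """Keep an edge only if it ranks in the top-k by score for both endpoints."""
    drop = []
    for u, v in g.edges:
        for node, other in ((u, v), (v, u)):
            ranked = sorted(
                g.neighbors(node),
                key=lambda w: _edge_sort_key(g, node, w),
                reverse=True,
            )
            if other not in ranked[:k]:
                drop.append((u, v))
                break
    g.remove_edges_from(drop)


def _reduce_components(g: nx.Graph, max_size: int) -> None:
    """Iteratively remove the lowest-score edge of any oversized component."""
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_size]
        if not oversized:
            return
        for comp in oversized:
            sub_edges = [(u, v) for u, v in g.edges(comp)]
            u, v = min(sub_edges, key=lambda e: _edge_sort_key(g, *e))
            g.remove_edge(u, v)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, str(path))


def export_edges_tsv(net: nx.Graph, path: str | Path) -> None:
    """Deterministic TSV edge table: identical network, identical bytes."""
    lines = ["source\ttarget\tscore\tn_matched\tdelta_parent_mass"]
    edges = sorted((tuple(sorted((u, v))), d) for u, v, d in net.edges(data=True))
    for (u, v), d in edges:
        lines.append(f"{u}\t{v}\t{d['score']:.6f}\t{d['n_matched']}\t{d['delta_parent_mass']:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_nodes_tsv(net: nx.Graph, path: str | Path) -> None:
    lines = ["id\tprecursor_mz"]
    for n in sorted(net.nodes):
        lines.append(f"{n}\t{net.nodes[n]['precursor_mz']:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
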