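"""Feature-based molecular networking: modified cosine and topology filters.

The modified cosine allows a fragment of one spectrum to match a fragment of
the other either directly or offset by the difference of the precursor
masses, so that related compounds differing by one substituent still align.
Peaks are paired one-to-one, greedily by descending score contribution
(sqrt-intensity weighting by default); on toy problems the greedy matching is
checked against the exhaustive optimum in the test-suite.

Network construction follows standard feature-based molecular networking
practice: keep edges with cosine > 0.65 and more than 4 matched peaks, then
keep an edge only if each node is in the other's top 10 most similar
neighbours, then prune lowest-scoring edges until every molecular family
(connected component) has at most 100 members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .rules import FRAGMENT_TOL
from .spectra import Spectrum

__all__ = ["modified_cosine", "build_network", "export_graphml", "export_edgelist"]


def _weights(s: Spectrum, intensity_power: float) -> list[float]:
    return [i ** intensity_power for i in s.intensity]


def modified_cosine(s1: Spectrum, s2: Spectrum,
                    frag_tol: float = FRAGMENT_TOL,
                    intensity_power: float = 0.5) -> tuple[float, int]:
    """Modified cosine similarity and matched-peak count of two spectra.

    Candidate pairs are peaks matching directly or shifted by the precursor
    mass difference; a deterministic greedy one-to-one assignment takes pairs
    by descending weight product, preferring direct over shifted matches and
    lower m/z on ties.  Score is in [0, 1]; empty spectra give (0.0, 0).
    """
    if s1.is_empty or s2.is_empty:
        return 0.0, 0
    w1 = _weights(s1, intensity_power)
    w2 = _weights(s2, intensity_power)
    shift = s1.precursor_mz - s2.precursor_mz
    candidates: list[tuple[float, int, float, int, int]] = []
    for i, mz1 in enumerate(s1.mz):
        for j, mz2 in enumerate(s2.mz):
            direct = abs(mz1 - mz2) <= frag_tol
            shifted = abs((mz1 - mz2) - shift) <= frag_tol
            if direct or shifted:
                # (-product, shifted-first flag, mz, i, j) sorts the best
                # product first, direct before shifted, then lower m/z
                candidates.append((-(w1[i] * w2[j]), 0 if direct else 1, mz1, i, j))
    candidates.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    total = 0.0
    matched = 0
    for negprod, _, _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        total += -negprod
        matched += 1
    norm = math.sqrt(sum(w * w for w in w1)) * math.sqrt(sum(w * w for w in w2))
    if norm == 0:
        return 0.0, 0
    return min(total / norm, 1.0), matched


def build_network(spectra: list[Spectrum],
                  min_score: float = 0.65,
                  min_matched: int = 4,
                  top_k: int = 10,
                  max_family: int = 100,
                  frag_tol: float = FRAGMENT_TOL,
                  intensity_power: float = 0.5) -> nx.Graph:
    """Build the molecular network over a list of spectra.

    Filters, in order: (1) score > ``min_score`` and matched peaks >
    ``min_matched`` (strictly more); (2) mutual top-``top_k`` rank; (3)
    iterative removal of the lowest-scoring edge inside any family larger
    than ``max_family``.  Nodes carry precursor m/z and RT attributes.
    """
    g = nx.Graph()
    for s in spectra:
        g.add_node(s.feature_id, precursor_mz=s.precursor_mz,
                   retention_time=s.retention_time)
    scored: list[tuple[str, str, float, int]] = []
    for a in range(len(spectra)):
        for b in range(a + 1, len(spectra)):
            score, matched = modified_cosine(spectra[a], spectra[b],
                                             frag_tol, intensity_power)
            if score > min_score and matched > min_matched:
                scored.append((spectra[a].feature_id, spectra[b].feature_id,
                               score, matched))

    # mutual top-k: each node ranks its filtered neighbours by score
    ranks: dict[str, list[tuple[float, str]]] = {}
    for u, v, score, _ in scored:
        ranks.setdefault(u, []).append((-score, v))
        ranks.setdefault(v, []).append((-score, u))
    topk: dict[str, set[str]] = {}
    for node, lst in ranks.items():
        lst.sort()
        topk[node] = {v for _, v in lst[:top_k]}
    for u, v, score, matched in scored:
        if v in topk.get(u, set()) and u in topk.get(v, set()):
            g.add_edge(u, v, score=score, matched_peaks=matched)

    _prune_families(g, max_family)
    return g


def _prune_families(g: nx.Graph, max_family: int) -> None:
    """Remove lowest-scoring edges until all components are <= max_family."""
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_family]
        if not oversized:
            return
        for comp in oversized:
            edges = [(d["score"], u, v) for u, v, d in g.subgraph(comp).edges(data=True)]
            edges.sort()
            g.remove_edge(edges[0][1], edges[0][2])


def export_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))


def export_edgelist(g: nx.Graph, path) -> None:
    """Edge list TSV: source, target, cosine score, matched peak count."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tscore\tmatched_peaks\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['score']:.4f}\t{d['matched_peaks']}\n")
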