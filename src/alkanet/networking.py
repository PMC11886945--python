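"""Feature-based molecular network construction and molecular families.

Nodes are LC-MS features; an edge connects two features whose MS/MS spectra
score at least ``min_cosine`` with at least ``min_matched`` matched peaks
under the modified cosine.  Connected components with two or more nodes are
the *molecular families* ("molecular networks", MN1, MN2, ...); isolated
nodes are singletons, reported separately.

Two optional topology filters mirror the hosted networking services: a
mutual top-k rule (an edge survives only if each endpoint ranks the other
within its k best neighbours) and a component-size cap that strips the
globally weakest edges out of oversized components.  Both are off by
default because only the cosine and matched-peak thresholds are part of the
published parameter set.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .similarity import modified_cosine
from .spectra import MsmsSpectrum

logger = logging.getLogger(__name__)


def build_network(
    spectra: Sequence[MsmsSpectrum],
    min_cosine: float = 0.7,
    min_matched: int = 6,
    frag_tol: float = 0.01,
    top_k: int | None = None,
    max_component: int | None = None,
) -> nx.Graph:
    """Score all spectrum pairs and keep edges passing both thresholds.

    Returns an undirected :class:`networkx.Graph` whose nodes are feature ids
    (with ``precursor_mz`` and ``rt`` attributes) and whose edges carry
    ``score``, ``matched_peaks`` and ``precursor_delta``.  Deterministic for
    a fixed input order.
    """
    if not 0 < min_cosine <= 1:
        raise ValueError("min_cosine must be in (0, 1]")
    if min_matched < 1:
        raise ValueError("min_matched must be >= 1")
    g = nx.Graph()
    usable = []
    for s in spectra:
        g.add_node(s.feature_id, precursor_mz=float(s.precursor_mz), rt=float(s.rt))
        if s.is_empty():
            logger.warning("feature %s has an empty spectrum; excluded from scoring", s.feature_id)
        else:
            usable.append(s)
    if len(usable) < 2:
        warnings.warn("fewer than 2 usable spectra; returning an edgeless network")
        return g
    for a, b in combinations(usable, 2):
        res = modified_cosine(a, b, frag_tol=frag_tol, allow_shift=True)
        if res.score >= min_cosine and res.matched_peaks >= min_matched:
            g.add_edge(
                a.feature_id,
                b.feature_id,
                score=float(res.score),
                matched_peaks=int(res.matched_peaks),
                precursor_delta=float(res.precursor_delta),
            )
    if top_k is not None:
        _apply_mutual_top_k(g, top_k)
    if max_component is not None:
        _cap_component_size(g, max_component)
    return g


def _apply_mutual_top_k(g: nx.Graph, k: int) -> None:
    """Keep an edge only if each endpoint ranks the other within its top k."""
    if k < 1:
        raise ValueError("top_k must be >= 1")
    # an edge must be in BOTH endpoints' top-k lists
    counts: dict[tuple, int] = {}
    for node in g.nodes:
        ranked = sorted(
            g.edges(node, data=True),
            key=lambda e: (-e[2]["score"], str(e[1])),
        )[:k]
        for u, v, _ in ranked:
            key = (min(u, v, key=str), max(u, v, key=str))
            counts[key] = counts.get(key, 0) + 1
    drop = [
        (u, v)
        for u, v in list(g.edges)
        if counts.get((min(u, v, key=str), max(u, v, key=str)), 0) < 2
    ]
    g.remove_edges_from(drop)


def _cap_component_size(g: nx.Graph, max_size: int) -> None:
    """Remove globally lowest-score edges from oversized components."""
    if max_size < 1:
        raise ValueError("max_component must be >= 1")
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_size]
        if not oversized:
            return
        cand = [
            (d["score"], str(min(u, v, key=str)), str(max(u, v, key=str)), u, v)
            for comp in oversized
            for u, v, d in g.subgraph(comp).edges(data=True)
        ]
        cand.sort()
        _, _, _, u, v = cand[0]
        g.remove_edge(u, v)


def molecular_families(g: nx.Graph, min_size: int = 2) -> tuple[list[list], list]:
    """Connected components with >= ``min_size`` nodes, plus singletons.

    Families are sorted by size descending, ties by smallest feature id;
    nodes inside a family are sorted by id.  Returns ``(families,
    singletons)``; when ``min_size == 1`` the two lists together partition
    the node set with every isolated node counted once (as a size-1 family).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    families = [c for c in comps if len(c) >= min_size]
    families.sort(key=lambda c: (-len(c), str(c[0])))
    singletons = sorted((c[0] for c in comps if len(c) == 1), key=str)
    if min_size <= 1:
        singletons = []
    return families, singletons


def attach_node_metadata(g: nx.Graph, metadata: pd.DataFrame) -> None:
    """Copy columns of a feature-indexed DataFrame onto node attributes."""
    for fid, row in metadata.iterrows():
        if fid in g:
            for key, val in row.items():
                if pd.notna(val):
                    g.nodes[fid][str(key)] = val


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """CSV edge list: source, target, score, matched_peaks, precursor_delta."""
    rows = [
        {
            "source": u,
            "target": v,
            "score": d.get("score"),
            "matched_peaks": d.get("matched_peaks"),
            "precursor_delta": d.get("precursor_delta"),
        }
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["source", "target", "score", "matched_peaks", "precursor_delta"]).to_csv(
        path, index=False
    )
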