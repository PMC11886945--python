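"""Spectral-library dereplication: exact/analog matching, repository search,
and delta-mass annotation propagation through the molecular network.

*Exact* matches require the library precursor to sit within the precursor
tolerance of the query and are scored with the plain cosine.  *Analog*
matches allow a larger precursor offset (an unknown analog of a known
compound) and are scored with the modified cosine, so fragment peaks and
neutral losses both contribute.  The repository-style search
(:func:`masst_search`) applies the same matching contract against a local
spectrum index carrying taxon metadata and aggregates the hits into
per-species/genus/family counts — an empty aggregate is the "no match
anywhere" novelty signal that green-lights isolation effort.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .similarity import modified_cosine, plain_cosine
from .spectra import MsmsSpectrum, read_mgf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryRecord:
    """One reference spectrum with compound and source metadata."""

    library_id: str
    name: str
    spectrum: MsmsSpectrum
    smiles: str | None = None
    adduct: str | None = None
    species: str | None = None
    genus: str | None = None
    family: str | None = None
    dataset: str | None = None


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str
    library_id: str
    name: str
    score: float
    matched_peaks: int
    match_type: str  # exact | analog | repository
    precursor_delta: float
    metadata: dict = field(default_factory=dict, compare=False)


def load_library(mgf_path: str | Path, metadata_csv: str | Path | None = None) -> list[LibraryRecord]:
    """Load a reference library from MGF plus an optional metadata CSV.

    The CSV is keyed by ``library_id`` (matching the MGF feature ids) with
    optional columns name, smiles, adduct, species, genus, family, dataset.
    """
    spectra = read_mgf(mgf_path)
    meta: dict[str, dict] = {}
    if metadata_csv is not None:
        df = pd.read_csv(metadata_csv, dtype=str)
        if "library_id" not in df.columns:
            raise ValueError("library metadata CSV is missing required column 'library_id'")
        meta = df.set_index("library_id").to_dict(orient="index")
    records = []
    for s in spectra:
        m = {k: v for k, v in meta.get(s.feature_id, {}).items() if pd.notna(v)}
        records.append(
            LibraryRecord(
                library_id=s.feature_id,
                name=m.get("name", s.feature_id),
                spectrum=s,
                smiles=m.get("smiles"),
                adduct=m.get("adduct"),
                species=m.get("species"),
                genus=m.get("genus"),
                family=m.get("family"),
                dataset=m.get("dataset"),
            )
        )
    ids = [r.library_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_id values in library MGF")
    return records


def library_search(
    queries: Sequence[MsmsSpectrum],
    library: Sequence[LibraryRecord],
    prec_tol: float = 0.01,
    frag_tol: float = 0.01,
    min_cosine: float = 0.7,
    min_matched: int = 6,
    mode: str = "exact",
    max_delta: float = 100.0,
) -> list[AnnotationHit]:
    """Match query spectra against a reference library.

    ``mode='exact'`` scores only records within ``prec_tol`` of the query
    precursor using the plain cosine; ``mode='analog'`` scores records within
    ``max_delta`` using the modified cosine (neutral-loss aware).  Hits below
    ``min_cosine`` or ``min_matched`` are discarded; surviving hits are
    sorted per query by score descending.
    """
    if mode not in ("exact", "analog"):
        raise ValueError(f"mode must be 'exact' or 'analog', got {mode!r}")
    if mode == "analog" and max_delta <= 0:
        raise ValueError("analog mode requires max_delta > 0")
    if not library:
        warnings.warn("library is empty; no hits possible")
        return []
    hits: list[AnnotationHit] = []
    for q in queries:
        if q.is_empty():
            continue
        q_hits = []
        for rec in library:
            delta = q.precursor_mz - rec.spectrum.precursor_mz
            if mode == "exact":
                if abs(delta) > prec_tol:
                    continue
                res = plain_cosine(q, rec.spectrum, frag_tol=frag_tol)
            else:
                if abs(delta) > max_delta:
                    continue
                res = modified_cosine(q, rec.spectrum, frag_tol=frag_tol, allow_shift=True)
            if res.score >= min_cosine and res.matched_peaks >= min_matched:
                q_hits.append(
                    AnnotationHit(
                        feature_id=q.feature_id,
                        library_id=rec.library_id,
                        name=rec.name,
                        score=float(res.score),
                        matched_peaks=int(res.matched_peaks),
                        match_type=mode,
                        precursor_delta=float(delta),
                        metadata={
                            k: v
                            for k, v in (
                                ("smiles", rec.smiles),
                                ("adduct", rec.adduct),
                                ("species", rec.species),
                                ("genus", rec.genus),
                                ("family", rec.family),
                                ("dataset", rec.dataset),
                            )
                            if v is not None
                        },
                    )
                )
        q_hits.sort(key=lambda h: (-h.score, h.library_id))
        hits.extend(q_hits)
    return hits


@dataclass(frozen=True)
class MasstResult:
    """Repository search outcome: raw hits plus taxon aggregation."""

    hits: tuple[AnnotationHit, ...]
    species_counts: dict
    genus_counts: dict
    family_counts: dict

    @property
    def is_novel(self) -> bool:
        """True when nothing in the index matched (a structural-novelty signal)."""
        return len(self.hits) == 0


def masst_search(
    query: MsmsSpectrum,
    index: Sequence[LibraryRecord],
    prec_tol: float = 0.05,
    frag_tol: float = 0.05,
    min_cosine: float = 0.7,
    min_matched: int = 3,
    analog: bool = False,
    max_delta: float = 100.0,
) -> MasstResult:
    """Search one spectrum against a local repository-style index.

    Defaults mirror the public repository search services: precursor and
    fragment tolerance 0.05 Da, cosine threshold 0.7, at least 3 matched
    peaks, analog search off.  Hit metadata is aggregated into per-species,
    per-genus and per-family match counts (distinct matched spectra per
    taxon), the table a plant-repository search returns.
    """
    hits = library_search(
        [query],
        index,
        prec_tol=prec_tol,
        frag_tol=frag_tol,
        min_cosine=min_cosine,
        min_matched=min_matched,
        mode="analog" if analog else "exact",
        max_delta=max_delta,
    )
    hits = [dataclasses.replace(h, match_type="repository") for h in hits]
    species: dict[str, int] = {}
    genus: dict[str, int] = {}
    family: dict[str, int] = {}
    for h in hits:
        for level, store in (("species", species), ("genus", genus), ("family", family)):
            taxon = h.metadata.get(level)
            if taxon:
                store[taxon] = store.get(taxon, 0) + 1
    return MasstResult(tuple(hits), species, genus, family)


def propagate_delta_annotations(
    net: nx.Graph,
    confirmed: Sequence[AnnotationHit],
    mass_deltas: pd.DataFrame,
    delta_tol: float = 0.01,
) -> pd.DataFrame:
    """Propagate confirmed annotations one hop along network edges.

    For each unannotated neighbour of a confirmed node, emit a provisional
    annotation carrying the parent compound, the edge precursor delta, the
    best-matching modification label within ``delta_tol`` Da (empty when none
    matches) and the edge score.  Neighbours adjacent to several confirmed
    nodes get one candidate per parent, ranked by edge score.  Single hop
    only: provisional annotations are never themselves propagated, and a
    confirmed node is never overwritten.
    """
    if mass_deltas is None or len(mass_deltas) == 0:
        raise ValueError("mass_deltas table must be nonempty")
    confirmed_ids = {h.feature_id for h in confirmed}
    for h in confirmed:
        if h.feature_id not in net:
            raise ValueError(f"confirmed hit for feature {h.feature_id!r} absent from network")
    rows = []
    for h in confirmed:
        for neighbor in net.neighbors(h.feature_id):
            if neighbor in confirmed_ids:
                continue
            edge = net.edges[h.feature_id, neighbor]
            delta = _signed_edge_delta(net, h.feature_id, neighbor, edge)
            label = _best_delta_label(abs(delta), mass_deltas, delta_tol)
            rows.append(
                {
                    "feature_id": neighbor,
                    "parent_feature": h.feature_id,
                    "parent_compound": h.name,
                    "precursor_delta": delta,
                    "delta_label": label,
                    "edge_score": edge.get("score", float("nan")),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "parent_feature",
            "parent_compound",
            "precursor_delta",
            "delta_label",
            "edge_score",
        ],
    )
    if len(out):
        out = out.sort_values(
            ["feature_id", "edge_score", "parent_feature"],
            ascending=[True, False, True],
        ).reset_index(drop=True)
    return out


def _signed_edge_delta(net: nx.Graph, parent, child, edge) -> float:
    """Precursor delta oriented child - parent, from node or edge attributes."""
    pm_parent = net.nodes[parent].get("precursor_mz")
    pm_child = net.nodes[child].get("precursor_mz")
    if pm_parent is not None and pm_child is not None:
        return float(pm_child) - float(pm_parent)
    return float(edge.get("precursor_delta", 0.0))


def _best_delta_label(abs_delta: float, mass_deltas: pd.DataFrame, tol: float) -> str:
    diffs = (mass_deltas["delta_da"] - abs_delta).abs()
    best = diffs.idxmin()
    if diffs.loc[best] <= tol:
        return str(mass_deltas.loc[best, "label"])
    return ""


def hits_to_frame(hits: Iterable[AnnotationHit]) -> pd.DataFrame:
    """Flatten hits to a DataFrame for CSV export."""
    rows = []
    for h in hits:
        row = {
            "feature_id": h.feature_id,
            "library_id": h.library_id,
            "name": h.name,
            "score": h.score,
            "matched_peaks": h.matched_peaks,
            "match_type": h.match_type,
            "precursor_delta": h.precursor_delta,
        }
        row.update(h.metadata)
        rows.append(row)
    return pd.DataFrame(rows)
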