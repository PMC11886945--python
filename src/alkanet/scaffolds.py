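"""Literature-report mining: scaffold substructure assignment, curation, and
the genus x scaffold presence matrix.

A :class:`ScaffoldQuery` names a core substructure (SMILES or SMARTS), a list
of *exclusion* substructures whose presence vetoes the assignment (classes a
loose substructure query also catches but that belong elsewhere), and a
curation blocklist of known-bad literature records.  Reports flow through

    load_reports -> assign_scaffolds -> curate_reports -> build_presence_matrix

ending in a genus-level boolean matrix with per-cell supporting report ids,
ready to map onto a phylogeny.  Stereochemistry is ignored throughout —
scaffold patterns are achiral.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # unparsable report structures are quarantined, not spammed

_DATA_DIR = Path(__file__).parent / "data"


class PatternError(ValueError):
    """A scaffold inclusion/exclusion pattern failed to compile."""


@dataclass(frozen=True)
class BlocklistEntry:
    species_pattern: str  # fnmatch-style glob against the species name
    compound_pattern: str  # glob against compound name, else canonical SMILES
    reason: str


@dataclass(frozen=True)
class ScaffoldQuery:
    """A named scaffold substructure with exclusions and curation blocklist."""

    name: str
    inclusion: str
    exclusions: tuple[str, ...] = ()
    blocklist: tuple[BlocklistEntry, ...] = ()

    def inclusion_mol(self) -> Chem.Mol:
        return _compile_pattern(self.inclusion, f"{self.name} inclusion")

    def exclusion_mols(self) -> list[Chem.Mol]:
        return [
            _compile_pattern(p, f"{self.name} exclusion {i}")
            for i, p in enumerate(self.exclusions)
        ]


def _compile_pattern(pattern: str, context: str) -> Chem.Mol:
    if not pattern or not pattern.strip():
        raise PatternError(f"{context}: empty pattern")
    mol = Chem.MolFromSmiles(pattern)
    if mol is None:
        mol = Chem.MolFromSmarts(pattern)
    if mol is None:
        raise PatternError(f"{context}: cannot parse {pattern!r} as SMILES or SMARTS")
    return mol


def load_scaffold_queries(path: str | Path | None = None) -> list[ScaffoldQuery]:
    """Load scaffold definitions from YAML; default: the five shipped queries."""
    path = Path(path) if path is not None else _DATA_DIR / "scaffolds.yaml"
    raw = yaml.safe_load(Path(path).read_text())
    queries = []
    for entry in raw["scaffolds"]:
        block = tuple(
            BlocklistEntry(b["species"], b.get("compound", "*"), b.get("reason", "curated out"))
            for b in entry.get("blocklist", [])
        )
        q = ScaffoldQuery(
            name=entry["name"],
            inclusion=entry["inclusion"],
            exclusions=tuple(entry.get("exclusions", [])),
            blocklist=block,
        )
        q.inclusion_mol()  # fail fast on bad data files
        q.exclusion_mols()
        queries.append(q)
    return queries


# ---------------------------------------------------------------------------
# SPARQL templating
# ---------------------------------------------------------------------------

_SPARQL_WIKIDATA = """\
# Natural products containing the {name} scaffold and the plant taxa they
# were reported from.  Substructure search is delegated to the IDSM/Sachem
# chemistry service; taxon occurrence comes from the "found in taxon"
# statements with their literature provenance.
PREFIX wdt: <http://www.wikidata.org/prop/direct/>
PREFIX p: <http://www.wikidata.org/prop/>
PREFIX ps: <http://www.wikidata.org/prop/statement/>
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX pr: <http://www.wikidata.org/prop/reference/>
PREFIX sachem: <http://bioinfo.uochb.cas.cz/rdf/v1.0/sachem#>
PREFIX idsm: <https://idsm.elixir-czech.cz/sparql/endpoint/>

SELECT DISTINCT ?compound ?compoundLabel ?smiles ?taxon ?taxonLabel ?reference WHERE {{
  SERVICE idsm:wikidata {{
    ?compound sachem:substructureSearch [ sachem:query "{scaffold_smiles}" ] .
  }}
  ?compound wdt:P233 ?smiles .                      # canonical SMILES
  ?compound p:P703 ?statement .                     # found in taxon
  ?statement ps:P703 ?taxon .
  OPTIONAL {{ ?statement prov:wasDerivedFrom/pr:P248 ?reference . }}
  SERVICE wikibase:label {{ bd:serviceParam wikibase:language "en" . }}
}}
"""

_SPARQL_DIALECTS = {"wikidata": _SPARQL_WIKIDATA}


def generate_sparql(q: ScaffoldQuery, endpoint_dialect: str = "wikidata") -> str:
    """Emit the parameterised query text for one scaffold (no network call).

    Byte-stable for fixed inputs; unknown dialects raise with the supported
    list.
    """
    q.inclusion_mol()  # validates the pattern (empty/broken -> PatternError)
    template = _SPARQL_DIALECTS.get(endpoint_dialect)
    if template is None:
        raise ValueError(
            f"unknown SPARQL dialect {endpoint_dialect!r}; supported: "
            f"{sorted(_SPARQL_DIALECTS)}"
        )
    return template.format(name=q.name, scaffold_smiles=q.inclusion)


# ---------------------------------------------------------------------------
# Occurrence reports
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceReport:
    """One literature record of a compound isolated from a species."""

    smiles: str  # canonical form
    species: str
    genus: str
    references: tuple[str, ...]
    family: str = ""
    order: str = ""
    compound_name: str = ""
    flags: tuple[str, ...] = ()
    scaffolds: tuple[str, ...] = ()  # filled by assign_scaffolds
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)


def load_reports(
    path: str | Path, reject_path: str | Path | None = None
) -> tuple[list[OccurrenceReport], pd.DataFrame]:
    """Load a literature-report CSV into canonicalised, deduplicated reports.

    Required columns: ``structure`` (SMILES), ``species``, ``reference``.
    Optional: ``genus`` (else first token of species), ``family``, ``order``,
    ``compound_name``, ``flags`` (semicolon-separated, e.g. ``lacks-NMR``).
    Duplicate (canonical structure, species) rows collapse into one report
    with merged references.  Rows whose structure does not parse are returned
    as the quarantine frame (and written to ``reject_path`` when given),
    never dropped silently.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("structure", "species", "reference"):
        if col not in df.columns:
            raise ValueError(f"report table is missing required column {col!r}")
    rejects = []
    merged: dict[tuple[str, str], OccurrenceReport] = {}
    for idx, row in df.iterrows():
        mol = Chem.MolFromSmiles(row["structure"]) if row["structure"] else None
        if mol is None:
            rejects.append({"row": idx, **row.to_dict(), "problem": "unparsable structure"})
            continue
        if not row["species"].strip():
            rejects.append({"row": idx, **row.to_dict(), "problem": "empty species"})
            continue
        canonical = Chem.MolToSmiles(mol)
        species = row["species"].strip()
        key = (canonical, species)
        genus = (row.get("genus") or "").strip() or species.split()[0].split("_")[0]
        flags = tuple(f for f in (row.get("flags") or "").split(";") if f)
        if key in merged:
            rep = merged[key]
            rep.references = tuple(dict.fromkeys(rep.references + (row["reference"],)))
            rep.flags = tuple(dict.fromkeys(rep.flags + flags))
        else:
            merged[key] = OccurrenceReport(
                smiles=canonical,
                species=species,
                genus=genus,
                references=(row["reference"],),
                family=(row.get("family") or "").strip(),
                order=(row.get("order") or "").strip(),
                compound_name=(row.get("compound_name") or "").strip(),
                flags=flags,
                mol=mol,
            )
    reject_df = pd.DataFrame(rejects)
    if reject_path is not None and len(reject_df):
        reject_df.to_csv(reject_path, index=False)
    return list(merged.values()), reject_df


def assign_scaffolds(
    reports: list[OccurrenceReport], queries: list[ScaffoldQuery]
) -> list[OccurrenceReport]:
    """Tag each report with every scaffold it contains.

    A report carries scaffold S iff its structure contains S's inclusion
    substructure and none of S's exclusion substructures (standard subgraph
    matching on the molecular graph).  Deterministic and order-independent.
    """
    compiled = []
    for q in queries:
        compiled.append((q.name, q.inclusion_mol(), q.exclusion_mols()))
    for rep in reports:
        mol = rep.mol if rep.mol is not None else Chem.MolFromSmiles(rep.smiles)
        if mol is None:
            raise ValueError(f"report structure failed to parse: {rep.smiles!r}")
        assigned = []
        for name, incl, excls in compiled:
            if not mol.HasSubstructMatch(incl):
                continue
            if any(mol.HasSubstructMatch(e) for e in excls):
                continue
            assigned.append(name)
        rep.scaffolds = tuple(assigned)
    return reports


def curate_reports(
    reports: list[OccurrenceReport], queries: list[ScaffoldQuery]
) -> tuple[list[OccurrenceReport], pd.DataFrame]:
    """Apply curation blocklists and the lacks-NMR rule; return audit log.

    A report is removed when it matches any (species pattern, compound
    pattern) blocklist entry of a scaffold it was assigned, or when flagged
    ``lacks-NMR``.  Every removal is logged with its reason.
    """
    block_by_scaffold = {q.name: q.blocklist for q in queries}
    kept = []
    audit = []
    for rep in reports:
        reason = None
        if "lacks-NMR" in rep.flags:
            reason = "no NMR data in original report"
        else:
            for scaf in rep.scaffolds:
                for entry in block_by_scaffold.get(scaf, ()):
                    target = rep.compound_name or rep.smiles
                    if fnmatch.fnmatch(rep.species, entry.species_pattern) and fnmatch.fnmatch(
                        target, entry.compound_pattern
                    ):
                        reason = entry.reason
                        break
                if reason:
                    break
        if reason:
            audit.append(
                {
                    "species": rep.species,
                    "compound": rep.compound_name or rep.smiles,
                    "scaffolds": ";".join(rep.scaffolds),
                    "reason": reason,
                }
            )
        else:
            kept.append(rep)
    return kept, pd.DataFrame(audit, columns=["species", "compound", "scaffolds", "reason"])


@dataclass
class PresenceMatrix:
    """Genus x scaffold booleans with per-cell supporting report references."""

    matrix: pd.DataFrame  # bool, index genus, columns scaffold names
    support: dict  # (genus, scaffold) -> tuple of reference ids
    genus_taxonomy: pd.DataFrame  # genus -> family, order (may be blank)

    def scaffold_summary(self) -> pd.DataFrame:
        """Distinct genus/family/order counts per scaffold."""
        rows = []
        for scaf in self.matrix.columns:
            genera = self.matrix.index[self.matrix[scaf]]
            tax = self.genus_taxonomy.loc[self.genus_taxonomy.index.intersection(genera)]
            rows.append(
                {
                    "scaffold": scaf,
                    "n_genera": int(len(genera)),
                    "n_families": int(tax["family"].replace("", pd.NA).dropna().nunique()),
                    "n_orders": int(tax["order"].replace("", pd.NA).dropna().nunique()),
                }
            )
        return pd.DataFrame(rows)

    def all_scaffold_genera(self) -> list[str]:
        """Genera positive for every scaffold column (e.g. the Piper signal)."""
        if self.matrix.empty:
            return []
        return sorted(self.matrix.index[self.matrix.all(axis=1)])


def build_presence_matrix(reports: list[OccurrenceReport]) -> PresenceMatrix:
    """Genus-level OR over curated reports, keeping per-cell support ids."""
    genera = sorted({r.genus for r in reports if r.scaffolds})
    scaffolds = sorted({s for r in reports for s in r.scaffolds})
    matrix = pd.DataFrame(False, index=pd.Index(genera, name="genus"), columns=scaffolds)
    support: dict[tuple[str, str], tuple[str, ...]] = {}
    taxonomy: dict[str, dict] = {}
    for rep in reports:
        if not rep.scaffolds:
            continue
        tax = taxonomy.setdefault(rep.genus, {"family": "", "order": ""})
        tax["family"] = tax["family"] or rep.family
        tax["order"] = tax["order"] or rep.order
        for scaf in rep.scaffolds:
            matrix.loc[rep.genus, scaf] = True
            prev = support.get((rep.genus, scaf), ())
            support[(rep.genus, scaf)] = tuple(dict.fromkeys(prev + rep.references))
    tax_df = pd.DataFrame.from_dict(taxonomy, orient="index").reindex(genera).fillna("")
    tax_df.index.name = "genus"
    return PresenceMatrix(matrix=matrix, support=support, genus_taxonomy=tax_df)
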