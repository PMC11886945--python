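"""Scaffold substructure assignment, SPARQL templating, curation, presence matrix."""

import shutil
import subprocess

import pandas as pd
import pytest
from rdkit import Chem

from alkanet import (
    ScaffoldQuery,
    assign_scaffolds,
    build_presence_matrix,
    curate_reports,
    generate_sparql,
    load_reports,
    load_scaffold_queries,
)
from alkanet.scaffolds import BlocklistEntry, OccurrenceReport, PatternError

PIPERINE = "O=C(/C=C/C=C/c1ccc2OCOc2c1)N1CCCCC1"


def report(smiles, species, scaffolds=(), flags=(), name="", refs=("R1",)):
    mol = Chem.MolFromSmiles(smiles)
    return OccurrenceReport(
        smiles=Chem.MolToSmiles(mol),
        species=species,
        genus=species.split()[0],
        references=tuple(refs),
        family=f"{species.split()[0]}aceae",
        order=f"{species.split()[0]}ales",
        compound_name=name,
        flags=tuple(flags),
        scaffolds=tuple(scaffolds),
        mol=mol,
    )


@pytest.fixture(scope="module")
def queries():
    return load_scaffold_queries()


class TestSparql:
    def test_contains_scaffold_literal(self, queries):
        q = next(q for q in queries if q.name == "piperidine")
        text = generate_sparql(q)
        assert q.inclusion in text
        assert "SELECT" in text

    def test_byte_stable(self, queries):
        assert generate_sparql(queries[0]) == generate_sparql(queries[0])

    def test_empty_pattern_rejected(self):
        with pytest.raises(PatternError):
            generate_sparql(ScaffoldQuery(name="bad", inclusion=""))

    def test_unknown_dialect_lists_supported(self, queries):
        with pytest.raises(ValueError, match="wikidata"):
            generate_sparql(queries[0], endpoint_dialect="virtuoso")


class TestLoadReports:
    def test_duplicates_collapse_with_merged_references(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "structure,species,reference\n"
            f"{PIPERINE},Piper nigrum,REF1\n"
            f"{PIPERINE},Piper nigrum,REF2\n"
        )
        reports, rejects = load_reports(p)
        assert len(reports) == 1
        assert reports[0].references == ("REF1", "REF2")
        assert len(rejects) == 0

    def test_unparsable_structures_are_quarantined(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "structure,species,reference\n"
            "not_a_smiles(((,Piper nigrum,REF1\n"
            f"{PIPERINE},Piper nigrum,REF2\n"
        )
        reports, rejects = load_reports(p, tmp_path / "rejects.csv")
        assert len(reports) == 1
        assert len(rejects) == 1
        assert (tmp_path / "rejects.csv").exists()

    def test_genus_defaults_to_first_species_token(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(f"structure,species,reference\n{PIPERINE},Piper nigrum,REF1\n")
        reports, _ = load_reports(p)
        assert reports[0].genus == "Piper"

    def test_missing_required_column_named(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("structure,reference\nCCO,R1\n")
        with pytest.raises(ValueError, match="species"):
            load_reports(p)


class TestAssign:
    def test_scaffold_itself_is_assigned(self, queries):
        for q in queries:
            rep = report(q.inclusion, "Testus exemplaris")
            (out,) = assign_scaffolds([rep], [q])
            assert out.scaffolds == (q.name,)

    def test_piperine_contains_piperidine_ring(self, queries):
        (out,) = assign_scaffolds([report(PIPERINE, "Piper nigrum")], queries)
        assert "piperidine" in out.scaffolds

    def test_exclusion_substructure_vetoes(self, queries):
        quinolizidine = "C1CCN2CCCCC2C1"
        (out,) = assign_scaffolds([report(quinolizidine, "Lupinus albus")], queries)
        assert "piperidine" not in out.scaffolds

    def test_aporphine_core_not_counted_as_benzylisoquinoline(self, queries):
        apomorphine = "CN1CCc2cccc3c2C1Cc1ccc(O)c(O)c1-3"
        (out,) = assign_scaffolds([report(apomorphine, "Papaver somniferum")], queries)
        assert "aporphine" in out.scaffolds
        assert "benzylisoquinoline" not in out.scaffolds

    def test_order_independent(self, queries):
        reps = [report(PIPERINE, "Piper nigrum"), report("CCO", "Vitis vinifera")]
        fwd = [r.scaffolds for r in assign_scaffolds(list(reps), queries)]
        rev = [r.scaffolds for r in assign_scaffolds(list(reps[::-1]), queries)][::-1]
        assert fwd == rev

    def test_empty_exclusions_superset_property(self):
        q_full = ScaffoldQuery("pip", "C1CCNCC1", exclusions=("C1CCN2CCCCC2C1",))
        q_none = ScaffoldQuery("pip", "C1CCNCC1")
        structures = [PIPERINE, "C1CCN2CCCCC2C1", "C1CCNCC1", "CCO"]
        reps = [report(s, "X y") for s in structures]
        with_excl = {r.smiles for r in assign_scaffolds([report(s, "X y") for s in structures], [q_full]) if r.scaffolds}
        without = {r.smiles for r in assign_scaffolds(reps, [q_none]) if r.scaffolds}
        assert with_excl <= without

    def test_broken_pattern_names_scaffold(self):
        q = ScaffoldQuery("broken", "C1CC")  # unclosed ring
        with pytest.raises(PatternError, match="broken"):
            assign_scaffolds([report("CCO", "X y")], [q])


@pytest.mark.skipif(shutil.which("obabel") is None, reason="Open Babel not on PATH")
def test_substructure_agrees_with_openbabel(queries):
    """Cross-check RDKit substructure calls with a second implementation."""
    cases = [(PIPERINE, "C1CCNCC1", True), ("c1ccncc1", "C1CCNCC1", False)]
    for structure, pattern, expected in cases:
        out = subprocess.run(
            ["obabel", f"-:{structure}", "-osmi", "--filter", f"s='{pattern}'"],
            capture_output=True,
            text=True,
        )
        matched = bool(out.stdout.strip())
        assert matched == expected


class TestCurate:
    def test_blocklisted_species_compound_removed_with_reason(self, queries):
        rep = report(PIPERINE, "Capsicum annuum", scaffolds=("piperidine",), name="piperine")
        kept, audit = curate_reports([rep], queries)
        assert kept == []
        assert "database error" in audit.iloc[0]["reason"]

    def test_lacks_nmr_flag_removes_report(self, queries):
        rep = report(PIPERINE, "Piper nigrum", scaffolds=("piperidine",), flags=("lacks-NMR",))
        kept, audit = curate_reports([rep], queries)
        assert kept == []
        assert "NMR" in audit.iloc[0]["reason"]

    def test_clean_reports_pass_unchanged(self, queries):
        rep = report(PIPERINE, "Piper nigrum", scaffolds=("piperidine",), name="piperine")
        kept, audit = curate_reports([rep], queries)
        assert len(kept) == 1 and len(audit) == 0

    def test_counts_non_increasing_through_curation(self, queries):
        reps = [
            report(PIPERINE, "Piper nigrum", scaffolds=("piperidine",), name="piperine"),
            report(PIPERINE, "Capsicum annuum", scaffolds=("piperidine",), name="piperine"),
        ]
        before = build_presence_matrix(list(reps))
        kept, _ = curate_reports(reps, queries)
        after = build_presence_matrix(kept)
        assert len(after.matrix) <= len(before.matrix)


class TestPresenceMatrix:
    def test_genus_level_or_with_support(self):
        reps = [
            report(PIPERINE, "Piper nigrum", scaffolds=("piperidine",), refs=("REF1",)),
            report(PIPERINE, "Piper longum", scaffolds=("piperidine",), refs=("REF2",)),
        ]
        m = build_presence_matrix(reps)
        assert bool(m.matrix.loc["Piper", "piperidine"])
        assert set(m.support[("Piper", "piperidine")]) == {"REF1", "REF2"}

    def test_genus_without_surviving_reports_absent(self):
        reps = [report("CCO", "Vitis vinifera", scaffolds=())]
        m = build_presence_matrix(reps)
        assert "Vitis" not in m.matrix.index

    def test_all_scaffold_genus_flagged(self):
        scafs = ["a", "b", "c"]
        reps = [report(PIPERINE, "Piper nigrum", scaffolds=(s,)) for s in scafs]
        reps += [report(PIPERINE, "Vitis vinifera", scaffolds=("a",))]
        m = build_presence_matrix(reps)
        assert m.all_scaffold_genera() == ["Piper"]
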