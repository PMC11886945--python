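"""Library matching (exact/analog), repository search and delta propagation."""

import networkx as nx
import numpy as np
import pytest

from alkanet import (
    LibraryRecord,
    library_search,
    masst_search,
    propagate_delta_annotations,
)
from alkanet.masses import default_mass_deltas, formula_mass

from conftest import make_spectrum

BASE_PEAKS = [(60.0 + 18 * i, 1.0 + 0.3 * i) for i in range(8)]


def record(lid, name, precursor, peaks, **meta):
    return LibraryRecord(
        library_id=lid, name=name, spectrum=make_spectrum(lid, precursor, peaks), **meta
    )


@pytest.fixture
def library():
    return [
        record("L1", "piperine-like", 286.14, BASE_PEAKS, species="Piper nigrum", genus="Piper", family="Piperaceae"),
        record("L2", "unrelated", 410.0, [(300.0, 1.0), (330.0, 1.0), (360.0, 1.0), (390.0, 1.0), (395.0, 1.0), (399.0, 1.0)]),
    ]


class TestLibrarySearch:
    def test_identical_query_is_perfect_exact_hit(self, library):
        q = make_spectrum("q", 286.14, BASE_PEAKS)
        hits = library_search([q], library, mode="exact")
        assert len(hits) == 1
        assert hits[0].library_id == "L1"
        assert hits[0].score == pytest.approx(1.0, abs=1e-9)
        assert hits[0].match_type == "exact"

    def test_methylated_analog_found_only_by_analog_mode(self, library):
        ch2 = formula_mass("CH2")
        shifted = [(mz + ch2, inten) for mz, inten in BASE_PEAKS]
        q = make_spectrum("q", 286.14 + ch2, shifted)
        assert library_search([q], library, mode="exact", prec_tol=0.01) == []
        hits = library_search([q], library, mode="analog", max_delta=100.0)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(1.0, abs=1e-9)
        assert hits[0].precursor_delta == pytest.approx(ch2, abs=1e-6)

    def test_record_outside_precursor_window_not_scored(self, library):
        q = make_spectrum("q", 286.34, BASE_PEAKS)  # 0.2 Da off
        assert library_search([q], library, mode="exact", prec_tol=0.01) == []

    def test_exact_hits_subset_of_analog_hits(self, library):
        q = make_spectrum("q", 286.14, BASE_PEAKS)
        exact = library_search([q], library, mode="exact")
        analog = library_search([q], library, mode="analog", max_delta=100.0)
        assert {h.library_id for h in exact} <= {h.library_id for h in analog}

    def test_empty_library_warns(self):
        q = make_spectrum("q", 286.14, BASE_PEAKS)
        with pytest.warns(UserWarning, match="empty"):
            assert library_search([q], []) == []


class TestMasst:
    def test_verbatim_spectrum_aggregates_one_species(self, library):
        q = make_spectrum("q", 286.14, BASE_PEAKS)
        res = masst_search(q, library)
        assert res.species_counts == {"Piper nigrum": 1}
        assert res.genus_counts == {"Piper": 1}
        assert not res.is_novel

    def test_no_match_is_novelty_signal(self, library):
        q = make_spectrum("q", 500.0, [(450.0, 1.0), (470.0, 1.0), (480.0, 1.0)])
        res = masst_search(q, library)
        assert res.is_novel
        assert res.species_counts == {}

    def test_two_species_one_genus(self):
        index = [
            record("L1", "x", 286.14, BASE_PEAKS, species="Piper nigrum", genus="Piper"),
            record("L2", "x", 286.14, BASE_PEAKS, species="Piper longum", genus="Piper"),
        ]
        res = masst_search(make_spectrum("q", 286.14, BASE_PEAKS), index)
        assert len(res.species_counts) == 2
        assert len(res.genus_counts) == 1
        assert res.genus_counts["Piper"] == 2

    def test_default_min_matched_is_three(self, library):
        # 3 intense shared peaks: cosine ~0.76, passes the repository default
        # (>= 3 matched peaks) but would fail networking's 6-peak floor
        q = make_spectrum("q", 286.14, BASE_PEAKS[-3:])
        res = masst_search(q, library)
        assert len(res.hits) == 1
        assert res.hits[0].matched_peaks == 3
        assert masst_search(q, library, min_matched=6).is_novel


class TestPropagation:
    def build_net(self):
        g = nx.Graph()
        g.add_node("root", precursor_mz=317.16)
        g.add_node("plus2h", precursor_mz=317.16 + formula_mass("H2"))
        g.add_node("odd", precursor_mz=317.16 + 1.2345)
        g.add_node("far", precursor_mz=500.0)
        g.add_edge("root", "plus2h", score=0.95, matched_peaks=8)
        g.add_edge("root", "odd", score=0.8, matched_peaks=7)
        return g

    def hit(self, fid="root"):
        from alkanet import AnnotationHit

        return AnnotationHit(fid, "L1", "piperlongumine", 0.97, 8, "exact", 0.0)

    def test_neighbor_at_h2_delta_gets_labeled_candidate(self):
        out = propagate_delta_annotations(self.build_net(), [self.hit()], default_mass_deltas())
        row = out[out.feature_id == "plus2h"].iloc[0]
        assert row.delta_label == "H2"
        assert row.parent_compound == "piperlongumine"
        assert row.precursor_delta == pytest.approx(formula_mass("H2"), abs=1e-9)

    def test_unmatched_delta_emitted_with_empty_label(self):
        out = propagate_delta_annotations(self.build_net(), [self.hit()], default_mass_deltas())
        row = out[out.feature_id == "odd"].iloc[0]
        assert row.delta_label == ""

    def test_non_neighbors_and_confirmed_nodes_get_no_rows(self):
        out = propagate_delta_annotations(self.build_net(), [self.hit()], default_mass_deltas())
        assert "far" not in set(out.feature_id)
        assert "root" not in set(out.feature_id)

    def test_confirmed_node_missing_from_network_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            propagate_delta_annotations(self.build_net(), [self.hit("ghost")], default_mass_deltas())

    def test_empty_delta_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="nonempty"):
            propagate_delta_annotations(
                self.build_net(), [self.hit()], pd.DataFrame(columns=["label", "delta_da"])
            )
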