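"""Tree loading, genus-level annotation, order pruning and iTOL export."""

import pandas as pd
import pytest

from alkanet import annotate_tree, export_itol, genus_token, load_tree
from alkanet.scaffolds import PresenceMatrix

NEWICK = "((Piper_sp:1,Peperomia_sp:1):1,(Punica_sp:2,(Vitis_sp:1,Rosa_sp:1):1):1);"

BACKBONE = pd.DataFrame(
    {
        "genus": ["Piper", "Peperomia", "Punica", "Vitis", "Rosa"],
        "family": ["Piperaceae", "Piperaceae", "Lythraceae", "Vitaceae", "Rosaceae"],
        "order": ["Piperales", "Piperales", "Myrtales", "Vitales", "Rosales"],
    }
)


def matrix(rows: dict, scaffolds=("piperidine", "aporphine")) -> PresenceMatrix:
    m = pd.DataFrame(False, index=pd.Index(sorted(rows), name="genus"), columns=list(scaffolds))
    support = {}
    for genus, positives in rows.items():
        for s in positives:
            m.loc[genus, s] = True
            support[(genus, s)] = ("REF1",)
    tax = pd.DataFrame({"family": "", "order": ""}, index=m.index)
    return PresenceMatrix(matrix=m, support=support, genus_taxonomy=tax)


class TestLoadTree:
    def test_parses_leaves_and_genera(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(NEWICK)
        gt = load_tree(p)
        assert len(gt.leaf_labels) == 5
        assert set(gt.genera) == {"Piper", "Peperomia", "Punica", "Vitis", "Rosa"}

    def test_space_delimited_label(self):
        assert genus_token("Piper betle") == "Piper"
        assert genus_token("Piper_betle") == "Piper"

    def test_duplicate_leaf_names_rejected(self, tmp_path):
        p = tmp_path / "dup.nwk"
        p.write_text("((Piper_sp:1,Piper_sp:1):1,Rosa_sp:1);")
        with pytest.raises(ValueError, match="duplicate"):
            load_tree(p)

    def test_unbalanced_newick_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((Piper_sp:1,Rosa_sp:1;")
        with pytest.raises(ValueError):
            load_tree(p)


class TestAnnotate:
    def make_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(NEWICK)
        return load_tree(p)

    def test_present_genus_gets_vector(self, tmp_path):
        gt = self.make_tree(tmp_path)
        ann = annotate_tree(gt, matrix({"Piper": ["piperidine"]}))
        assert bool(ann.presence.loc["Piper_sp", "piperidine"])
        assert not ann.presence.loc["Rosa_sp"].any()

    def test_absent_genus_reported_unmapped(self, tmp_path):
        gt = self.make_tree(tmp_path)
        m = matrix({"Piper": ["piperidine"], "Ghostus": ["aporphine"]})
        ann = annotate_tree(gt, m)
        assert ann.unmapped_genera == ["Ghostus"]
        # conservation: mapped + unmapped = matrix genera
        mapped = set(m.matrix.index) & set(gt.genera)
        assert mapped | set(ann.unmapped_genera) == set(m.matrix.index)

    def test_prune_drops_orders_without_reports(self, tmp_path):
        gt = self.make_tree(tmp_path)
        m = matrix({"Piper": ["piperidine"], "Punica": ["piperidine"]})
        ann = annotate_tree(gt, m, backbone=BACKBONE, prune=True)
        genera = {genus_token(l) for l in ann.leaf_labels}
        assert genera == {"Piper", "Peperomia", "Punica"}  # Vitales/Rosales pruned
        assert "Rosa_sp" not in ann.leaf_labels

    def test_prune_is_idempotent(self, tmp_path):
        gt = self.make_tree(tmp_path)
        m = matrix({"Piper": ["piperidine"]})
        once = annotate_tree(gt, m, backbone=BACKBONE, prune=True)
        twice = annotate_tree(once, m, backbone=BACKBONE, prune=True)
        assert sorted(once.leaf_labels) == sorted(twice.leaf_labels)

    def test_prune_without_backbone_is_error(self, tmp_path):
        gt = self.make_tree(tmp_path)
        with pytest.raises(ValueError, match="backbone"):
            annotate_tree(gt, matrix({"Piper": ["piperidine"]}), prune=True)


class TestExport:
    def test_one_file_per_scaffold_plus_tree(self, tmp_path):
        gt = load_tree_from(tmp_path)
        ann = annotate_tree(gt, matrix({"Piper": ["piperidine", "aporphine"]}))
        files = export_itol(ann, tmp_path / "itol")
        names = sorted(f.name for f in files)
        assert names == ["itol_aporphine.txt", "itol_piperidine.txt", "tree.nwk"]

    def test_negative_leaves_absent_from_data_block(self, tmp_path):
        gt = load_tree_from(tmp_path)
        ann = annotate_tree(gt, matrix({"Piper": ["piperidine"]}))
        files = export_itol(ann, tmp_path / "itol")
        content = next(f for f in files if "piperidine" in f.name).read_text()
        data = content.split("DATA\n", 1)[1]
        assert "Piper_sp,1" in data
        assert "Rosa_sp" not in data
        assert "Rosa_sp" in files[-1].read_text()  # still in the tree

    def test_itol_header_conforms_to_binary_template(self, tmp_path):
        gt = load_tree_from(tmp_path)
        ann = annotate_tree(gt, matrix({"Piper": ["piperidine"]}))
        files = export_itol(ann, tmp_path / "itol")
        lines = files[0].read_text().splitlines()
        assert lines[0] == "DATASET_BINARY"
        for key in ("SEPARATOR", "DATASET_LABEL", "FIELD_SHAPES", "FIELD_LABELS", "DATA"):
            assert any(l.startswith(key) for l in lines)

    def test_reexport_is_byte_identical(self, tmp_path):
        gt = load_tree_from(tmp_path)
        ann = annotate_tree(gt, matrix({"Piper": ["piperidine"]}))
        f1 = export_itol(ann, tmp_path / "a")
        f2 = export_itol(ann, tmp_path / "b")
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()


def load_tree_from(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text(NEWICK)
    return load_tree(p)
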