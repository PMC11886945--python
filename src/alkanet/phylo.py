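"""Genus-level phylogeny mapping and iTOL annotation export.

The reference tree carries one representative species per genus, so scaffold
presence is attached at the genus token (the first underscore- or
space-delimited token of each leaf label).  Orders come from a user-supplied
genus -> family -> order backbone table, never from tree topology, because
Newick internal nodes carry no order labels.  Export writes one iTOL
``DATASET_BINARY`` plain-text file per scaffold plus the (optionally pruned)
Newick.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .scaffolds import PresenceMatrix

# iTOL symbol shapes cycle through these (2=circle, 1=square, 3=star, 4=right
# triangle, 5=left triangle); colors are a qualitative palette.
_ITOL_SHAPES = ("2", "1", "3", "4", "5", "6")
_ITOL_COLORS = ("#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#a65628")


@dataclass
class GenusTree:
    """A rooted genus-level tree with per-leaf genus tokens."""

    tree: dendropy.Tree
    presence: pd.DataFrame | None = None  # leaf label -> scaffold booleans
    unmapped_genera: list[str] = field(default_factory=list)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def genus_of_leaf(self) -> dict[str, str]:
        return {label: genus_token(label) for label in self.leaf_labels}

    @property
    def genera(self) -> list[str]:
        return sorted(set(self.genus_of_leaf.values()))


def genus_token(leaf_label: str) -> str:
    """First underscore- or space-delimited token of a leaf label."""
    return leaf_label.replace("_", " ").split()[0]


def load_tree(path: str | Path) -> GenusTree:
    """Parse a Newick genus-level tree (branch lengths, polytomies allowed)."""
    text = Path(path).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"cannot parse Newick file {path}: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dup = {x for x in labels if labels.count(x) > 1}
    if dup:
        raise ValueError(f"duplicate leaf names in tree: {sorted(dup)}")
    if any(not genus_token(x) for x in labels):
        raise ValueError("tree has a leaf with an empty label")
    return GenusTree(tree=tree)


def _near_miss(a: str, b: str) -> bool:
    """Case/diacritic-insensitive equality (for the curation report only)."""
    def norm(s: str) -> str:
        return "".join(
            c for c in unicodedata.normalize("NFD", s.lower()) if not unicodedata.combining(c)
        )
    return a != b and norm(a) == norm(b)


def annotate_tree(
    gt: GenusTree,
    m: PresenceMatrix,
    backbone: pd.DataFrame | None = None,
    prune: bool = False,
) -> GenusTree:
    """Attach each genus's scaffold vector to its leaf; optionally prune.

    Genus matching is case-sensitive exact on the genus token.  Matrix genera
    absent from the tree are collected into ``unmapped_genera`` (never
    silently dropped); a near-miss report (case/diacritic variants) is logged
    on the result as ``near_misses``.  With ``prune=True``, all leaves whose
    backbone order contains no positive genus are removed and unary internal
    nodes cleaned up; this requires a backbone covering every tree genus.
    """
    genus_of_leaf = gt.genus_of_leaf
    tree_genera = set(genus_of_leaf.values())
    matrix_genera = list(m.matrix.index)

    presence = pd.DataFrame(
        False, index=pd.Index(gt.leaf_labels, name="leaf"), columns=m.matrix.columns
    )
    for leaf, genus in genus_of_leaf.items():
        if genus in m.matrix.index:
            presence.loc[leaf] = m.matrix.loc[genus]

    unmapped = sorted(g for g in matrix_genera if g not in tree_genera)
    near = sorted(
        (g, t) for g in unmapped for t in tree_genera if _near_miss(g, t)
    )

    tree = gt.tree.clone(depth=1)
    if prune:
        if backbone is None:
            raise ValueError("pruning requires a genus->order backbone table")
        bb = backbone.set_index("genus") if "genus" in backbone.columns else backbone
        missing = sorted(tree_genera - set(bb.index))
        if missing:
            raise ValueError(f"backbone does not cover tree genera: {missing[:10]}")
        positive_genera = set(m.matrix.index[m.matrix.any(axis=1)]) & tree_genera
        positive_orders = {bb.loc[g, "order"] for g in positive_genera}
        keep_leaves = [
            leaf
            for leaf, genus in genus_of_leaf.items()
            if bb.loc[genus, "order"] in positive_orders
        ]
        taxa = [t for t in tree.taxon_namespace if t.label in set(keep_leaves)]
        tree.retain_taxa(taxa)
        presence = presence.loc[keep_leaves]

    out = GenusTree(tree=tree, presence=presence, unmapped_genera=unmapped)
    out.near_misses = near  # type: ignore[attr-defined]
    return out


def export_itol(gt: GenusTree, out_dir: str | Path) -> list[Path]:
    """Write one iTOL DATASET_BINARY file per scaffold plus the Newick tree.

    Leaves with an all-false vector stay in the tree but are omitted from the
    DATA blocks.  Deterministic: identical inputs produce identical bytes.
    """
    if gt.presence is None:
        raise ValueError("tree is not annotated; run annotate_tree first")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, scaffold in enumerate(gt.presence.columns):
        shape = _ITOL_SHAPES[i % len(_ITOL_SHAPES)]
        color = _ITOL_COLORS[i % len(_ITOL_COLORS)]
        lines = [
            "DATASET_BINARY",
            "SEPARATOR COMMA",
            f"DATASET_LABEL,{scaffold}",
            f"COLOR,{color}",
            f"FIELD_SHAPES,{shape}",
            f"FIELD_LABELS,{scaffold}",
            f"FIELD_COLORS,{color}",
            "DATA",
        ]
        col = gt.presence[scaffold]
        for leaf in gt.presence.index[col]:
            lines.append(f"{leaf},1")
        path = out_dir / f"itol_{scaffold}.txt"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    tree_path = out_dir / "tree.nwk"
    tree_path.write_text(
        gt.tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )
    written.append(tree_path)
    return written
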