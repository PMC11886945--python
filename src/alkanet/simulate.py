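"""Seeded synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the study conditions, not the physics: analog series
of MS/MS spectra that share fragment peaks and precursor-delta-shifted peaks
(planted molecular families), literature-report tables mixing decorated
scaffold structures with exclusion-substructure decoys, and a small
genus-labelled phylogeny with an order backbone.  One seed drives a single
NumPy generator in a fixed draw order, so identical configs give identical
fixtures on any platform.  Cross-group separation is enforced by exhaustive
pairwise rejection: a new family or decoy is redrawn until none of its peaks
comes within ``min_separation`` Da of any already-placed spectrum's peaks in
either the direct or the precursor-shifted frame.

Within a family, every member shifts the *same* mobile subset of base peaks
by its own modification delta — the fragments containing the modified moiety
are a property of the molecule, so analogs move the same peaks.  Between
groups no direct or shifted candidate pairing exists by construction, so
between-group modified-cosine scores are exactly zero while within-family
scores are near one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .masses import formula_mass
from .scaffolds import ScaffoldQuery, load_scaffold_queries
from .spectra import MsmsSpectrum

_DEFAULT_DELTAS = tuple(formula_mass(f) for f in ("H2", "CH2", "O", "C2H4", "CH2O"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for all fixture generators."""

    seed: int = 0
    # spectra
    n_families: int = 6
    family_size: tuple[int, int] = (3, 5)  # inclusive range, counts the base spectrum
    n_fragments: tuple[int, int] = (10, 14)
    precursor_range: tuple[float, float] = (250.0, 550.0)
    modification_deltas: tuple[float, ...] = _DEFAULT_DELTAS
    intensity_noise_sd: float = 0.05  # relative, multiplicative
    mz_jitter_sd: float = 0.002  # Da
    n_decoy_singletons: int = 5
    mobile_fraction: float = 0.4
    min_separation: float = 0.05  # Da margin between cross-group (shifted) positions
    # reports
    positives_per_scaffold: int = 4
    decoy_fraction: float = 0.4
    n_unmapped_genera: int = 1
    n_lacks_nmr: int = 1
    # tree
    tree_size: int = 24
    genera_per_order: int = 4

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_decoy_singletons < 0 or self.tree_size < 2:
            raise ValueError("counts must be nonnegative and tree_size >= 2")
        if self.family_size[0] > 0 and self.n_families == 0 and self.n_decoy_singletons == 0:
            raise ValueError("family_size > 0 requires at least one family or decoy")
        if self.intensity_noise_sd < 0 or self.mz_jitter_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.family_size[1] - 1 > len(self.modification_deltas):
            raise ValueError("family_size exceeds available modification deltas + base")


# ---------------------------------------------------------------------------
# Spectra with planted analog families
# ---------------------------------------------------------------------------

def _groups_aligned(
    peaks_a: np.ndarray, prec_a: float, peaks_b: np.ndarray, prec_b: float, margin: float
) -> bool:
    """True when any direct or precursor-shifted peak pairing comes within margin."""
    d = peaks_a[:, None] - peaks_b[None, :]
    delta = prec_a - prec_b
    return bool((np.abs(d) < margin).any() or (np.abs(d - delta) < margin).any())


def _base_peak_ok(
    x: float,
    is_mobile: bool,
    precursor: float,
    deltas: list[float],
    placed: list[tuple[np.ndarray, float]],
    own_members: list[list[float]],
    margin: float,
) -> bool:
    """Can base fragment x join the family without cross-group alignments?

    For every member (precursor + delta), the member's realised position (x,
    shifted when mobile) must stay >= margin away from every placed
    spectrum's peaks in both the direct and the precursor-shifted frame, and
    >= 0.5 Da from the member's own already-placed peaks.
    """
    for member_positions, delta in zip(own_members, deltas):
        pos = x + delta if is_mobile else x
        if any(abs(pos - p) < 0.5 for p in member_positions):
            return False
        pm = precursor + delta
        for other_mz, other_prec in placed:
            diff = np.abs(other_mz - pos)
            if diff.min() < margin:
                return False
            if np.abs(other_mz - pos + (pm - other_prec)).min() < margin:
                return False
    return True


def simulate_spectra(c: SimulationConfig) -> tuple[list[MsmsSpectrum], dict[str, int]]:
    """Planted analog families plus decoy singletons, with truth labels.

    Returns ``(spectra, labels)`` where labels maps feature_id to a family
    index; decoys get unique negative labels.  With zero noise and jitter,
    within-family modified-cosine scores are exactly 1; between-group scores
    are exactly 0 by construction (rejection sampling removes accidental
    direct or shifted alignments).
    """
    rng = np.random.default_rng(c.seed)
    margin = c.min_separation
    spectra: list[MsmsSpectrum] = []
    labels: dict[str, int] = {}
    placed: list[tuple[np.ndarray, float]] = []  # (peak positions, precursor) per spectrum

    for fam in range(c.n_families):
        n_frag = int(rng.integers(c.n_fragments[0], c.n_fragments[1] + 1))
        size = int(rng.integers(c.family_size[0], c.family_size[1] + 1))
        precursor = float(rng.uniform(*c.precursor_range))
        frag_hi = precursor - 20.0 - max(c.modification_deltas)
        deltas = [0.0] + [
            float(d) for d in rng.choice(c.modification_deltas, size=size - 1, replace=False)
        ]
        n_mobile = max(1, int(round(c.mobile_fraction * n_frag)))
        mobile_idx = set(rng.choice(n_frag, size=n_mobile, replace=False).tolist())
        base_mz: list[float] = []
        own_members: list[list[float]] = [[] for _ in deltas]
        for i in range(n_frag):
            is_mobile = i in mobile_idx
            for attempt in range(20000):
                x = float(rng.uniform(50.0, frag_hi))
                if _base_peak_ok(x, is_mobile, precursor, deltas, placed, own_members, margin):
                    break
            else:
                raise RuntimeError("could not place a separated family peak; loosen the config")
            base_mz.append(x)
            for member_positions, delta in zip(own_members, deltas):
                member_positions.append(x + delta if is_mobile else x)
        base_int = rng.lognormal(mean=10.0, sigma=1.0, size=n_frag)
        for k, delta in enumerate(deltas):
            mz = np.asarray(own_members[k])
            prec = precursor + delta
            noise = np.exp(rng.normal(0.0, c.intensity_noise_sd, size=n_frag))
            jitter = rng.normal(0.0, c.mz_jitter_sd, size=n_frag)
            fid = f"F{fam:02d}m{k}"
            order = np.argsort(mz + jitter)
            spectra.append(
                MsmsSpectrum(
                    feature_id=fid,
                    precursor_mz=prec,
                    mz=(mz + jitter)[order],
                    intensity=(base_int * noise)[order],
                    rt=float(rng.uniform(1.0, 20.0)),
                    provenance="synthetic-family",
                )
            )
            labels[fid] = fam
            placed.append((mz, prec))

    for d in range(c.n_decoy_singletons):
        n_frag = int(rng.integers(c.n_fragments[0], c.n_fragments[1] + 1))
        precursor = float(rng.uniform(*c.precursor_range))
        own: list[list[float]] = [[]]
        for i in range(n_frag):
            for attempt in range(20000):
                x = float(rng.uniform(50.0, precursor - 20.0))
                if _base_peak_ok(x, False, precursor, [0.0], placed, own, margin):
                    break
            else:
                raise RuntimeError("could not place a separated decoy peak; loosen the config")
            own[0].append(x)
        mz = np.sort(np.asarray(own[0]))
        fid = f"D{d:02d}"
        spectra.append(
            MsmsSpectrum(
                feature_id=fid,
                precursor_mz=precursor,
                mz=mz,
                intensity=rng.lognormal(mean=10.0, sigma=1.0, size=n_frag),
                rt=float(rng.uniform(1.0, 20.0)),
                provenance="synthetic-decoy",
            )
        )
        labels[fid] = -(d + 1)
        placed.append((mz, precursor))
    return spectra, labels


# ---------------------------------------------------------------------------
# Feature table (areas over organs + blanks) for the filter stage
# ---------------------------------------------------------------------------

def simulate_feature_table(
    c: SimulationConfig, spectra: list[MsmsSpectrum]
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, bool]]:
    """Peak-area table over 3 organs x 3 replicates + 2 blanks, with truth.

    Real features get areas in all samples of 1-2 organs; a planted minority
    is made blank-contaminated (fails the 3x rule) or under-replicated
    (detected in < 3 biological samples).  Returns (areas, sample metadata,
    truth) where truth maps feature_id -> should survive filtering.
    """
    rng = np.random.default_rng(c.seed + 1)
    organs = ["leaf", "stem", "root"]
    samples = [f"{o}_{r}" for o in organs for r in range(1, 4)] + ["blank_1", "blank_2"]
    meta = pd.DataFrame(
        {
            "role": ["biological"] * 9 + ["blank"] * 2,
            "organ": [o for o in organs for _ in range(3)] + ["none", "none"],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    rows = {}
    truth: dict[str, bool] = {}
    for i, s in enumerate(spectra):
        areas = np.zeros(len(samples))
        chosen = rng.choice(len(organs), size=int(rng.integers(1, 3)), replace=False)
        for o in chosen:
            areas[o * 3 : o * 3 + 3] = rng.lognormal(mean=13.0, sigma=0.5, size=3)
        kind = i % 5
        if kind == 3:  # blank-contaminated: best blank within 3x of best sample
            areas[9:] = areas.max() / rng.uniform(1.0, 2.5)
            truth[s.feature_id] = False
        elif kind == 4:  # under-replicated
            detected = np.flatnonzero(areas[:9] > 0)
            areas[detected[2:]] = 0.0
            areas[9:] = 0.0
            truth[s.feature_id] = False
        else:
            areas[9:] = areas.max() / rng.uniform(10.0, 100.0)  # faint blank carryover
            truth[s.feature_id] = True
        rows[s.feature_id] = areas
    areas_df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    areas_df.index.name = "feature_id"
    return areas_df, meta, truth


# ---------------------------------------------------------------------------
# Literature reports from decorated scaffolds
# ---------------------------------------------------------------------------

_SUBSTITUENTS = ("C", "OC", "O")  # methyl, methoxy, hydroxyl


def _decorate(rng: np.random.Generator, core: Chem.Mol, n_subs: int) -> Chem.Mol | None:
    """Attach simple substituents at random hydrogen-bearing atoms."""
    mol = Chem.RWMol(core)
    for _ in range(n_subs):
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetTotalNumHs() > 0 and a.GetSymbol() in ("C", "N")
        ]
        if not sites:
            break
        site = int(rng.choice(sites))
        frag = Chem.MolFromSmiles(str(rng.choice(_SUBSTITUENTS)))
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol, frag))
        mol.AddBond(site, offset, Chem.BondType.SINGLE)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _unambiguous_for(mol: Chem.Mol, target: str | None, queries: list[ScaffoldQuery]) -> bool:
    """True when the rule-based assignment of mol is exactly {target} (or {})."""
    assigned = set()
    for q in queries:
        if mol.HasSubstructMatch(q.inclusion_mol()) and not any(
            mol.HasSubstructMatch(e) for e in q.exclusion_mols()
        ):
            assigned.add(q.name)
    want = {target} if target else set()
    return assigned == want


def simulate_reports(
    c: SimulationConfig,
    queries: list[ScaffoldQuery] | None = None,
    tree_backbone: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Literature-report table with unambiguous truth assignments.

    Positives are scaffold cores decorated with methyl/methoxy/hydroxy
    substituents; decoys are the exclusion substructures themselves plus
    scaffold-free small molecules.  Species are drawn from the simulated
    tree's genera, with ``n_unmapped_genera`` extra genera absent from the
    tree (to exercise the unmapped-genus accounting).  Returns ``(reports,
    truth)``; truth has one row per report with its expected scaffold ("" for
    decoys).  Every emitted case is unambiguous: candidates whose rule-based
    assignment is not exactly the intended one are redrawn.
    """
    if queries is None:
        queries = load_scaffold_queries()
    rng = np.random.default_rng(c.seed + 2)
    if tree_backbone is None:
        _, tree_backbone = simulate_tree(c)
    genera = list(tree_backbone["genus"])
    extra = [f"Unplacedgenus{i}" for i in range(c.n_unmapped_genera)]
    bb = tree_backbone.set_index("genus")

    rows = []
    truth_rows = []
    ref_counter = 0

    def add_report(smiles: str, scaffold: str, genus: str, flags: str = "") -> None:
        nonlocal ref_counter
        ref_counter += 1
        if genus in bb.index:
            family, order = bb.loc[genus, "family"], bb.loc[genus, "order"]
        else:
            family, order = f"{genus}aceae", f"{genus}ales"
        species = f"{genus} syntheticum"
        rows.append(
            {
                "structure": smiles,
                "compound_name": f"cmpd{ref_counter:03d}",
                "species": species,
                "genus": genus,
                "family": family,
                "order": order,
                "reference": f"REF{ref_counter:04d}",
                "flags": flags,
            }
        )
        truth_rows.append({"structure": smiles, "species": species, "scaffold": scaffold})

    # guarantee each unmapped genus at least one positive report
    genus_pool = list(genera)
    pending_extra = list(extra)
    n_decoys = max(1, int(round(c.decoy_fraction * c.positives_per_scaffold)))
    lacks_budget = c.n_lacks_nmr
    for q in queries:
        core = Chem.MolFromSmiles(q.inclusion)
        if core is None:  # SMARTS-only inclusion: use first decoy-free positive impossible
            raise ValueError(f"scaffold {q.name}: inclusion must be a SMILES for simulation")
        for i in range(c.positives_per_scaffold):
            mol = None
            for _ in range(50):
                cand = _decorate(rng, core, int(rng.integers(0, 3)))
                if cand is not None and _unambiguous_for(cand, q.name, queries):
                    mol = cand
                    break
            if mol is None:
                mol = core  # bare scaffold always matches itself
            if pending_extra:
                genus = pending_extra.pop()
            else:
                genus = str(rng.choice(genus_pool))
            add_report(Chem.MolToSmiles(mol), q.name, genus)
        for j in range(n_decoys):
            if q.exclusions and j % 2 == 0:
                decoy = Chem.MolFromSmiles(q.exclusions[j // 2 % len(q.exclusions)])
                if decoy is None or not _unambiguous_for(decoy, None, queries):
                    decoy = Chem.MolFromSmiles("CCOC(=O)c1ccccc1")
            else:
                decoy = Chem.MolFromSmiles(
                    str(rng.choice(["CCO", "c1ccccc1O", "CC(=O)Oc1ccccc1C(=O)O", "OCC1OC(O)C(O)C(O)C1O"]))
                )
            if not _unambiguous_for(decoy, None, queries):
                continue
            flags = ""
            if lacks_budget > 0:
                flags = "lacks-NMR"
                lacks_budget -= 1
            add_report(Chem.MolToSmiles(decoy), "", str(rng.choice(genus_pool)), flags)

    reports = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return reports, truth


# ---------------------------------------------------------------------------
# Genus tree + backbone
# ---------------------------------------------------------------------------

def _random_newick(rng: np.random.Generator, leaves: list[str]) -> str:
    """Random bifurcating clade over the given leaves, with branch lengths."""
    nodes = [f"{leaf}:{rng.uniform(0.5, 2.0):.4f}" for leaf in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.5, 2.0):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def simulate_tree(c: SimulationConfig) -> tuple[str, pd.DataFrame]:
    """Random genus-level Newick tree plus its genus/family/order backbone.

    Genera are grouped into synthetic orders (clades of ``genera_per_order``
    leaves); each genus appears in exactly one order.  Deterministic bytes
    for a fixed config.
    """
    rng = np.random.default_rng(c.seed + 3)
    n_orders = (c.tree_size + c.genera_per_order - 1) // c.genera_per_order
    backbone_rows = []
    order_clades = []
    idx = 0
    for o in range(n_orders):
        leaves = []
        for _ in range(c.genera_per_order):
            if idx >= c.tree_size:
                break
            genus = f"Genus{chr(ord('a') + o)}{idx:02d}".capitalize()
            leaf = f"{genus}_representativa"
            leaves.append(leaf)
            backbone_rows.append(
                {"genus": genus, "family": f"Family{o:02d}{idx % 2}", "order": f"Order{o:02d}"}
            )
            idx += 1
        if leaves:
            order_clades.append(_random_newick(rng, leaves))
    while len(order_clades) > 1:
        i, j = sorted(rng.choice(len(order_clades), size=2, replace=False))
        merged = f"({order_clades[i]},{order_clades[j]}):{rng.uniform(0.5, 2.0):.4f}"
        order_clades = [n for k, n in enumerate(order_clades) if k not in (i, j)] + [merged]
    newick = order_clades[0] + ";\n"
    backbone = pd.DataFrame(backbone_rows, columns=["genus", "family", "order"])
    return newick, backbone


def write_fixtures(c: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every fixture in the formats the pipeline reads."""
    from .features import FeatureTable, write_feature_table
    from .spectra import write_mgf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra, labels = simulate_spectra(c)
    newick, backbone = simulate_tree(c)
    reports, truth = simulate_reports(c, tree_backbone=backbone)
    areas, meta, ft_truth = simulate_feature_table(c, spectra)

    paths = {
        "spectra": out / "spectra.mgf",
        "labels": out / "family_labels.csv",
        "areas": out / "feature_areas.csv",
        "samples": out / "samples.csv",
        "feature_truth": out / "feature_truth.csv",
        "reports": out / "reports.csv",
        "report_truth": out / "report_truth.csv",
        "tree": out / "tree.nwk",
        "backbone": out / "backbone.csv",
    }
    write_mgf(spectra, paths["spectra"])
    pd.Series(labels, name="family").rename_axis("feature_id").to_csv(paths["labels"])
    mzrt = pd.DataFrame(
        {"mz": [s.precursor_mz for s in spectra], "rt": [s.rt for s in spectra]},
        index=pd.Index([s.feature_id for s in spectra], name="feature_id"),
    )
    ft = FeatureTable(areas=areas, feature_meta=mzrt, sample_meta=meta)
    write_feature_table(ft, paths["areas"], paths["samples"])
    pd.Series(ft_truth, name="retained").rename_axis("feature_id").to_csv(paths["feature_truth"])
    reports.to_csv(paths["reports"], index=False)
    truth.to_csv(paths["report_truth"], index=False)
    paths["tree"].write_text(newick)
    backbone.to_csv(paths["backbone"], index=False)
    return paths
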