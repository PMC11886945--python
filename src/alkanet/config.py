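"""Pipeline configuration: one text (YAML) file, defaults = the published parameters."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    Parameter defaults are the values of the study workflow this pipeline
    replays: fragment tolerance 0.01 Da with cosine >= 0.7 and >= 6 matched
    peaks for networking and library matching, 0.02 Da replicate-merge
    tolerance, 3x blank fold-change with detection in >= 3 samples, and
    repository search at 0.05/0.05 Da, cosine 0.7, >= 3 matched peaks with
    analog search off.
    """

    # paths
    spectra_mgf: str | None = None
    feature_csv: str | None = None
    sample_csv: str | None = None
    library_mgf: str | None = None
    library_csv: str | None = None
    reports_csv: str | None = None
    tree_newick: str | None = None
    backbone_csv: str | None = None
    scaffolds_yaml: str | None = None
    out_dir: str = "alkanet_out"
    # spectral preprocessing / merging
    mz_tol_merge: float = 0.02
    precursor_window: float = 17.0
    window_size: float = 50.0
    window_top_k: int = 6
    # feature filters
    blank_fold: float = 3.0
    min_samples: int = 3
    # networking
    frag_tol_network: float = 0.01
    min_cosine: float = 0.7
    min_matched: int = 6
    top_k: int | None = None
    max_component: int | None = None
    # library search
    prec_tol_library: float = 0.01
    analog_max_delta: float = 100.0
    # repository (MASST-style) search
    masst_prec_tol: float = 0.05
    masst_frag_tol: float = 0.05
    masst_min_cosine: float = 0.7
    masst_min_matched: int = 3
    masst_analog: bool = False
    # phylogeny
    prune_orders: bool = True
    # simulation
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def overrides_from_defaults(self) -> dict:
        """Keys whose value differs from the published defaults (for run logs)."""
        default = PipelineConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(default, f.name)
        }
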