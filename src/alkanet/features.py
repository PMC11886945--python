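"""Feature quantification table: blank subtraction, replication filter, organ profiles.

A :class:`FeatureTable` holds the aligned feature x sample peak-area matrix
plus per-sample metadata (role ``blank``/``biological`` and, for biological
samples, the plant organ).  The two filters implemented here are the standard
untargeted-metabolomics cleanups applied after feature alignment:

* **blank fold-change** — a feature is kept only when its best biological
  signal is at least ``blank_fold`` times its best extraction-blank signal
  (default 3x); a feature absent from all blanks always passes,
* **replication** — a feature must be detected (area strictly > 0) in at
  least ``min_samples`` biological samples (default 3, matching triplicate
  injection per organ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLE_BLANK = "blank"
ROLE_BIOLOGICAL = "biological"


@dataclass
class FeatureTable:
    """Feature x sample peak areas with sample roles.

    ``areas`` is a DataFrame indexed by feature_id with one column per
    sample_id; ``feature_meta`` carries ``mz`` (Da) and ``rt`` (minutes) per
    feature; ``sample_meta`` is indexed by sample_id with columns ``role``
    (blank|biological) and ``organ`` (leaf|stem|root|none).
    """

    areas: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    removal_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.areas.index.has_duplicates:
            dups = self.areas.index[self.areas.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if not set(self.areas.columns) <= set(self.sample_meta.index):
            missing = set(self.areas.columns) - set(self.sample_meta.index)
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad_roles = set(self.sample_meta["role"]) - {ROLE_BLANK, ROLE_BIOLOGICAL}
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        if (self.areas.values < 0).any():
            raise ValueError("peak areas must be nonnegative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.index)

    def samples_with_role(self, role: str) -> list[str]:
        ids = self.sample_meta.index[self.sample_meta["role"] == role]
        return [s for s in self.areas.columns if s in set(ids)]

    @property
    def blank_samples(self) -> list[str]:
        return self.samples_with_role(ROLE_BLANK)

    @property
    def biological_samples(self) -> list[str]:
        return self.samples_with_role(ROLE_BIOLOGICAL)


def read_feature_table(areas_csv: str | Path, samples_csv: str | Path) -> FeatureTable:
    """Load a feature table CSV plus its sample-metadata sidecar CSV.

    ``areas_csv`` columns: feature_id, mz, rt, then one column per sample.
    ``samples_csv`` columns: sample_id, role, organ.
    """
    df = pd.read_csv(areas_csv, dtype={"feature_id": str})
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"feature table is missing required column {col!r}")
    df = df.set_index("feature_id")
    meta = pd.read_csv(samples_csv, dtype=str)
    for col in ("sample_id", "role"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata is missing required column {col!r}")
    if "organ" not in meta.columns:
        meta["organ"] = "none"
    meta = meta.fillna({"organ": "none"}).set_index("sample_id")
    sample_cols = [c for c in df.columns if c not in ("mz", "rt")]
    return FeatureTable(
        areas=df[sample_cols].astype(float),
        feature_meta=df[["mz", "rt"]].astype(float),
        sample_meta=meta[["role", "organ"]],
    )


def write_feature_table(t: FeatureTable, areas_csv: str | Path, samples_csv: str | Path) -> None:
    out = pd.concat([t.feature_meta, t.areas], axis=1)
    out.index.name = "feature_id"
    out.to_csv(areas_csv)
    meta = t.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(samples_csv)


def filter_feature_table(
    t: FeatureTable, blank_fold: float = 3.0, min_samples: int = 3
) -> FeatureTable:
    """Apply the blank fold-change and replication filters.

    A feature is retained iff both hold:

    * ``max(biological areas) >= blank_fold * max(blank areas)``, a feature
      with zero signal in every blank passing unconditionally, and
    * it is detected (area > 0) in at least ``min_samples`` biological
      samples.

    Removal reasons are recorded per feature on the returned table's
    ``removal_log``.
    """
    if blank_fold <= 0:
        raise ValueError("blank_fold must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    bio = t.biological_samples
    if not bio:
        raise ValueError("feature table has no biological samples")
    blanks = t.blank_samples

    bio_max = t.areas[bio].max(axis=1)
    blank_max = t.areas[blanks].max(axis=1) if blanks else pd.Series(0.0, index=t.areas.index)
    detected = (t.areas[bio] > 0).sum(axis=1)

    pass_blank = (blank_max == 0) | (bio_max >= blank_fold * blank_max)
    pass_repl = detected >= min_samples

    reasons = []
    for fid in t.areas.index:
        if not pass_blank.loc[fid]:
            reasons.append((fid, f"blank_fold<{blank_fold:g}"))
        if not pass_repl.loc[fid]:
            reasons.append((fid, f"detected_in<{min_samples}_samples"))
    keep = pass_blank & pass_repl
    log = pd.DataFrame(reasons, columns=["feature_id", "reason"])
    return FeatureTable(
        areas=t.areas.loc[keep],
        feature_meta=t.feature_meta.loc[keep],
        sample_meta=t.sample_meta,
        removal_log=log,
    )


def organ_abundance(t: FeatureTable, feature_ids: list[str] | None = None) -> pd.DataFrame:
    """Feature x organ matrix of log10 mean peak areas.

    The cell value is log10 of the mean area over the biological replicates
    of that organ; an organ whose mean is zero yields NaN (missing), never
    -inf.  Unknown feature ids raise ``KeyError``.
    """
    if feature_ids is None:
        feature_ids = t.feature_ids
    missing = [f for f in feature_ids if f not in t.areas.index]
    if missing:
        raise KeyError(f"unknown feature id(s): {missing}")
    bio_meta = t.sample_meta.loc[t.biological_samples]
    organs = [o for o in bio_meta["organ"].unique() if o != "none"]
    out = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"), columns=organs, dtype=float)
    for organ in organs:
        cols = bio_meta.index[bio_meta["organ"] == organ]
        means = t.areas.loc[feature_ids, cols].mean(axis=1)
        with np.errstate(divide="ignore"):
            vals = np.log10(means.to_numpy())
        vals[means.to_numpy() <= 0] = np.nan
        out[organ] = vals
    return out
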