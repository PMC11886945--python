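"""MS/MS spectrum container, MGF input/output and spectral preprocessing.

Spectra are feature-linked: each one carries the identifier of the LC-MS
feature it fragments, the convention used by feature-based molecular
networking (FBMN) exports from mzmine/GNPS.  The MGF dialect understood here
is that export dialect: ``PEPMASS``, ``RTINSECONDS``, ``CHARGE`` and
``FEATURE_ID`` headers per ``BEGIN IONS`` block.  Retention time is stored in
minutes internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf


class MgfParseError(ValueError):
    """Raised when an MGF block violates the expected dialect."""


@dataclass(frozen=True)
class MsmsSpectrum:
    """One feature's fragmentation spectrum.

    Parameters
    ----------
    feature_id:
        Opaque identifier linking the spectrum to an LC-MS feature.
    precursor_mz:
        Precursor ion m/z in Da; must be positive.
    mz, intensity:
        Fragment peak arrays; mz strictly ascending, intensities >= 0.
    rt:
        Retention time in minutes (nonnegative).
    charge:
        Precursor charge, small positive integer.
    provenance:
        Free-text sample/source tag.
    """

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    rt: float = 0.0
    charge: int = 1
    provenance: str = ""
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.shape != inten.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be nonnegative, got {self.rt}")
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")
        if np.any(inten < 0):
            raise ValueError("intensities must be nonnegative")
        if mz.size and np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            object.__setattr__(self, "mz", mz[order])
            object.__setattr__(self, "intensity", inten[order])
        object.__setattr__(self, "_validated", True)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        """Peak list as (mz, intensity) tuples, ascending mz."""
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def is_empty(self) -> bool:
        return self.mz.size == 0

    def with_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "MsmsSpectrum":
        return replace(self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))


def spectrum_from_peaks(
    feature_id: str,
    precursor_mz: float,
    peaks: Sequence[tuple[float, float]],
    **kwargs,
) -> MsmsSpectrum:
    """Build a spectrum from (mz, intensity) pairs in any order."""
    if peaks:
        arr = np.asarray(peaks, dtype=float).reshape(-1, 2)
    else:
        arr = np.empty((0, 2))
    return MsmsSpectrum(feature_id, precursor_mz, arr[:, 0], arr[:, 1], **kwargs)


# ---------------------------------------------------------------------------
# MGF I/O (mzmine/FBMN dialect, via pyteomics)
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read feature-linked MS/MS spectra from an MGF file.

    Feature ids come from the ``FEATURE_ID`` (or ``SCANS``) header when
    present, else the 1-based block ordinal.  A block without ``PEPMASS``
    raises :class:`MgfParseError` naming the block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[MsmsSpectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1, read_charges=False) as reader:
        for ordinal, entry in enumerate(reader, start=1):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MgfParseError(f"block {ordinal} has no PEPMASS")
            precursor = float(pepmass[0])
            fid = params.get("feature_id", params.get("scans"))
            feature_id = str(fid) if fid is not None else str(ordinal)
            rt_s = params.get("rtinseconds")
            rt_min = float(rt_s) / 60.0 if rt_s is not None else 0.0
            charge = params.get("charge")
            charge_i = int(charge[0]) if charge else 1
            spectra.append(
                MsmsSpectrum(
                    feature_id=feature_id,
                    precursor_mz=precursor,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    rt=rt_min,
                    charge=abs(charge_i) or 1,
                    provenance=str(path.name),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    """Write spectra in the mzmine/FBMN MGF dialect (deterministic bytes)."""
    path = Path(path)
    buf = io.StringIO()
    for s in spectra:
        buf.write("BEGIN IONS\n")
        buf.write(f"FEATURE_ID={s.feature_id}\n")
        buf.write(f"PEPMASS={s.precursor_mz:.4f}\n")
        buf.write(f"RTINSECONDS={s.rt * 60.0:.3f}\n")
        buf.write(f"CHARGE={s.charge}+\n")
        for mz, inten in zip(s.mz, s.intensity):
            buf.write(f"{mz:.5f} {inten:.6g}\n")
        buf.write("END IONS\n\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_spectrum(
    s: MsmsSpectrum,
    precursor_window: float = 17.0,
    window_size: float | None = 50.0,
    top_k: int | None = 6,
) -> MsmsSpectrum:
    """Remove precursor-region peaks and thin dense regions.

    Peaks within ``precursor_window`` Da of the precursor m/z are removed
    (they carry no fragment information and dominate the norm).  Then, within
    every sliding mz window of ``window_size`` Da, only the ``top_k`` most
    intense peaks are kept; a peak survives if it is among the top ``top_k``
    in the window centred on it.  Either stage can be disabled by passing 0 /
    ``None``.  An empty result is returned as an empty spectrum (callers
    exclude it from networking), never raised.
    """
    if precursor_window < 0:
        raise ValueError("precursor_window must be >= 0")
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    mz, inten = s.mz, s.intensity
    if precursor_window > 0:
        keep = np.abs(mz - s.precursor_mz) > precursor_window
        mz, inten = mz[keep], inten[keep]
    if top_k is not None and window_size:
        half = window_size / 2.0
        keep_idx = []
        for i in range(mz.size):
            in_win = np.abs(mz - mz[i]) <= half
            ranks = np.argsort(inten[in_win], kind="stable")[::-1][:top_k]
            winners = np.flatnonzero(in_win)[ranks]
            if i in winners:
                keep_idx.append(i)
        mz, inten = mz[keep_idx], inten[keep_idx]
    return s.with_peaks(mz, inten)


def merge_replicate_spectra(
    spectra: Sequence[MsmsSpectrum], mz_tol: float = 0.02
) -> MsmsSpectrum:
    """Merge per-sample replicate spectra of one feature into a consensus.

    Peaks within ``mz_tol`` Da across replicates are merged: the merged
    intensity is the *sum* of the member intensities, and the merged m/z is
    the intensity-weighted mean of the member m/z values.  The default
    tolerance is 0.02 Da, the expected mass deviation of an Orbitrap
    MS2 peak.  All inputs must share one feature id.
    """
    if not spectra:
        raise ValueError("no spectra to merge")
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    fids = {s.feature_id for s in spectra}
    if len(fids) != 1:
        raise ValueError(f"cannot merge spectra of different features: {sorted(fids)}")
    if len(spectra) == 1:
        return spectra[0]
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # single-linkage grouping along the sorted axis: a gap > mz_tol starts a
    # new merged peak
    merged_mz: list[float] = []
    merged_int: list[float] = []
    start = 0
    for i in range(1, mz.size + 1):
        if i == mz.size or mz[i] - mz[i - 1] > mz_tol:
            chunk_mz, chunk_int = mz[start:i], inten[start:i]
            total = chunk_int.sum()
            if total > 0:
                merged_mz.append(float(np.average(chunk_mz, weights=chunk_int)))
            else:
                merged_mz.append(float(chunk_mz.mean()))
            merged_int.append(float(total))
            start = i
    base = spectra[0]
    precursor = float(np.mean([s.precursor_mz for s in spectra]))
    return MsmsSpectrum(
        feature_id=base.feature_id,
        precursor_mz=precursor,
        mz=np.asarray(merged_mz),
        intensity=np.asarray(merged_int),
        rt=float(np.mean([s.rt for s in spectra])),
        charge=base.charge,
        provenance="merged",
    )
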