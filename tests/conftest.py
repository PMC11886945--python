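"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from alkanet import MsmsSpectrum, spectrum_from_peaks


def make_spectrum(feature_id, precursor, peaks, **kw) -> MsmsSpectrum:
    return spectrum_from_peaks(str(feature_id), float(precursor), peaks, **kw)


def random_spectrum(
    rng: np.random.Generator,
    feature_id: str,
    n_peaks: int,
    shared_positions: np.ndarray | None = None,
    precursor: float | None = None,
) -> MsmsSpectrum:
    """A random small spectrum; optionally reuses some shared peak positions
    so that pairs of spectra actually have candidate matches."""
    precursor = precursor if precursor is not None else float(rng.uniform(200, 500))
    mz = rng.uniform(50, precursor - 20, size=n_peaks)
    if shared_positions is not None and len(shared_positions):
        k = int(rng.integers(0, min(n_peaks, len(shared_positions)) + 1))
        if k:
            idx = rng.choice(len(shared_positions), size=k, replace=False)
            mz[:k] = shared_positions[idx] + rng.normal(0, 0.002, size=k)
    intensity = rng.uniform(0.1, 1.0, size=n_peaks)
    order = np.argsort(mz)
    return MsmsSpectrum(feature_id, precursor, mz[order], intensity[order])


def brute_force_modified_cosine(a, b, frag_tol=0.01, allow_shift=True, intensity_power=0.5):
    """Exhaustive maximum-weight one-to-one pairing oracle.

    Enumerates, peak by peak of spectrum a, every assignment of candidate
    partners in b (or no partner), and returns the maximal sum of products of
    the unit-normalised transformed intensities.  Exponential, usable only
    for tiny spectra; independent of the production implementation.
    """
    keep_a = a.intensity > 0
    keep_b = b.intensity > 0
    mza, ia = a.mz[keep_a], np.power(a.intensity[keep_a], intensity_power)
    mzb, ib = b.mz[keep_b], np.power(b.intensity[keep_b], intensity_power)
    ia = ia / np.linalg.norm(ia)
    ib = ib / np.linalg.norm(ib)
    delta = a.precursor_mz - b.precursor_mz
    candidates = []
    for i in range(len(mza)):
        row = []
        for j in range(len(mzb)):
            if abs(mza[i] - mzb[j]) <= frag_tol or (
                allow_shift and abs(mza[i] - mzb[j] - delta) <= frag_tol
            ):
                row.append(j)
        candidates.append(row)

    best = {"score": 0.0, "matched": 0}

    def recurse(i: int, used: set, score: float, matched: int) -> None:
        if i == len(mza):
            if score > best["score"] + 1e-15 or (
                abs(score - best["score"]) <= 1e-15 and matched > best["matched"]
            ):
                best["score"] = score
                best["matched"] = matched
            return
        recurse(i + 1, used, score, matched)  # leave peak i unmatched
        for j in candidates[i]:
            if j not in used:
                used.add(j)
                recurse(i + 1, used, score + ia[i] * ib[j], matched + 1)
                used.remove(j)

    recurse(0, set(), 0.0, 0)
    return min(best["score"], 1.0), best["matched"]


def clusters_to_labels(families, singletons, ids):
    """Map component membership to integer cluster labels per feature id."""
    member = {}
    for k, fam in enumerate(families):
        for node in fam:
            member[node] = k
    for k, node in enumerate(singletons):
        member[node] = 10_000 + k
    return [member[i] for i in ids]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
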