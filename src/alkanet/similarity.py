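"""Modified-cosine MS/MS similarity with exact one-to-one peak matching.

Two fragment peaks may be paired either *directly* (equal m/z within the
fragment tolerance) or *shifted* (m/z differing by the precursor mass
difference, capturing a shared neutral loss).  Intensities are square-root
transformed and each spectrum is scaled to unit Euclidean norm; the score is
the maximum, over all one-to-one pairings of candidate peak pairs, of the sum
of products of the normalised intensities.  That maximisation is solved
exactly as a rectangular assignment problem, so the score is the true optimum
rather than the greedy approximation — spectra are small enough that this
costs nothing.

With ``allow_shift=False`` only direct pairs are candidates and the score
reduces to the plain normalised dot product used for exact library matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import MsmsSpectrum

# Deterministic tie-break between equal-weight pairings: prefer the pair with
# the smaller |m/z residual|.  The bonus is far below the 1e-9 score
# tolerance, so it never changes which pairing is optimal by more than a tie.
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class SimilarityResult:
    """Outcome of scoring one spectrum pair."""

    score: float
    matched_peaks: int
    precursor_delta: float
    pairs: tuple[tuple[int, int, bool], ...]  # (index_a, index_b, shifted)

    def __post_init__(self) -> None:
        assert 0.0 <= self.score <= 1.0 + 1e-9
        assert self.matched_peaks == len(self.pairs)


def _normalised_weights(
    s: MsmsSpectrum, intensity_power: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nonzero-intensity peak m/z, unit-norm transformed weights, original indices."""
    keep = s.intensity > 0
    idx = np.flatnonzero(keep)
    mz = s.mz[keep]
    w = np.power(s.intensity[keep], intensity_power)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    return mz, w, idx


def modified_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    frag_tol: float = 0.01,
    allow_shift: bool = True,
    intensity_power: float = 0.5,
) -> SimilarityResult:
    """Score two spectra with the modified cosine.

    Parameters
    ----------
    frag_tol:
        Fragment m/z tolerance in Da (default 0.01, the networking value).
    allow_shift:
        When True, peaks offset by the precursor mass difference
        ``precursor_mz(a) - precursor_mz(b)`` are also candidate pairs.
    intensity_power:
        Exponent applied to intensities before normalisation; 0.5 is the
        networking convention, 1.0 scores raw intensities.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if a.is_empty() or b.is_empty():
        raise ValueError("cannot score an empty spectrum")
    delta = a.precursor_mz - b.precursor_mz
    mza, wa, idxa = _normalised_weights(a, intensity_power)
    mzb, wb, idxb = _normalised_weights(b, intensity_power)
    if mza.size == 0 or mzb.size == 0:
        raise ValueError("cannot score a spectrum with no nonzero-intensity peaks")

    dmz = mza[:, None] - mzb[None, :]
    direct = np.abs(dmz) <= frag_tol
    if allow_shift:
        shifted = np.abs(dmz - delta) <= frag_tol
    else:
        shifted = np.zeros_like(direct)
    candidate = direct | shifted
    if not candidate.any():
        return SimilarityResult(0.0, 0, delta, ())

    weight = np.where(candidate, wa[:, None] * wb[None, :], 0.0)
    residual = np.where(direct, np.abs(dmz), np.abs(dmz - delta))
    bonus = np.where(candidate, _TIE_EPS * (1.0 - np.minimum(residual / frag_tol, 1.0)), 0.0)
    rows, cols = linear_sum_assignment(weight + bonus, maximize=True)

    pairs = []
    score = 0.0
    for i, j in zip(rows, cols):
        if not candidate[i, j] or weight[i, j] <= 0.0:
            continue
        pairs.append((int(idxa[i]), int(idxb[j]), bool(not direct[i, j])))
        score += float(weight[i, j])
    score = min(score, 1.0)
    return SimilarityResult(score, len(pairs), delta, tuple(pairs))


def plain_cosine(
    a: MsmsSpectrum, b: MsmsSpectrum, frag_tol: float = 0.01, intensity_power: float = 0.5
) -> SimilarityResult:
    """Cosine similarity with direct peak matching only."""
    return modified_cosine(a, b, frag_tol=frag_tol, allow_shift=False, intensity_power=intensity_power)
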