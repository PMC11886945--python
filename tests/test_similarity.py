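"""Modified cosine: exactness against the brute-force oracle and invariants."""

import numpy as np
import pytest

from alkanet import modified_cosine, plain_cosine

from conftest import brute_force_modified_cosine, make_spectrum, random_spectrum


class TestKnownCases:
    def test_self_similarity_is_one(self, rng):
        s = random_spectrum(rng, "a", 6)
        res = modified_cosine(s, s)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.matched_peaks == s.n_peaks

    def test_disjoint_spectra_score_zero(self):
        a = make_spectrum("a", 300.0, [(100.0, 1.0), (120.0, 1.0)])
        b = make_spectrum("b", 300.0, [(150.0, 1.0), (170.0, 1.0)])
        for shift in (True, False):
            res = modified_cosine(a, b, allow_shift=shift)
            assert res.score == 0.0
            assert res.matched_peaks == 0

    def test_one_direct_one_shifted_pair_gives_unit_score(self):
        # b is a +20 Da analog: peak 100 matches directly, 140 = 120 + 20 shifted
        a = make_spectrum("a", 200.0, [(100.0, 1.0), (120.0, 1.0)])
        b = make_spectrum("b", 220.0, [(100.0, 1.0), (140.0, 1.0)])
        res = modified_cosine(a, b, frag_tol=0.01, allow_shift=True)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.matched_peaks == 2
        shifted_flags = sorted(p[2] for p in res.pairs)
        assert shifted_flags == [False, True]
        # oracle agrees this is the optimum over all one-to-one pairings
        oracle_score, _ = brute_force_modified_cosine(a, b)
        assert res.score == pytest.approx(oracle_score, abs=1e-9)

    def test_zero_intensity_peaks_are_ignored(self):
        a = make_spectrum("a", 300.0, [(100.0, 1.0), (150.0, 0.0)])
        b = make_spectrum("b", 300.0, [(100.0, 2.0), (150.0, 1.0)])
        res = modified_cosine(a, b)
        assert res.matched_peaks == 1
        assert all(ia == 0 for ia, _, _ in res.pairs)  # index into original peaks

    def test_empty_spectrum_is_contract_violation(self):
        a = make_spectrum("a", 300.0, [])
        b = make_spectrum("b", 300.0, [(100.0, 1.0)])
        with pytest.raises(ValueError, match="empty"):
            modified_cosine(a, b)


class TestOracleEquivalence:
    def test_equals_bruteforce_on_random_pairs(self, rng):
        shared = rng.uniform(60, 180, size=12)
        for trial in range(300):
            na, nb = rng.integers(2, 9, size=2)
            a = random_spectrum(rng, "a", int(na), shared)
            b = random_spectrum(rng, "b", int(nb), shared)
            res = modified_cosine(a, b)
            oracle, _ = brute_force_modified_cosine(a, b)
            assert res.score == pytest.approx(oracle, abs=1e-9), f"trial {trial}"

    def test_plain_cosine_equals_oracle_with_equal_precursors(self, rng):
        shared = rng.uniform(60, 180, size=10)
        for _ in range(200):
            a = random_spectrum(rng, "a", int(rng.integers(2, 9)), shared, precursor=320.0)
            b = random_spectrum(rng, "b", int(rng.integers(2, 9)), shared, precursor=320.0)
            res = plain_cosine(a, b)
            oracle, _ = brute_force_modified_cosine(a, b, allow_shift=False)
            assert res.score == pytest.approx(oracle, abs=1e-9)


class TestInvariants:
    def test_symmetry(self, rng):
        shared = rng.uniform(60, 180, size=10)
        for _ in range(100):
            a = random_spectrum(rng, "a", 6, shared)
            b = random_spectrum(rng, "b", 6, shared)
            ab = modified_cosine(a, b)
            ba = modified_cosine(b, a)
            assert ab.score == pytest.approx(ba.score, abs=1e-9)
            assert ab.precursor_delta == pytest.approx(-ba.precursor_delta)

    def test_scale_invariance(self, rng):
        shared = rng.uniform(60, 180, size=10)
        a = random_spectrum(rng, "a", 7, shared)
        b = random_spectrum(rng, "b", 7, shared)
        scaled = b.with_peaks(b.mz, b.intensity * 37.5)
        assert modified_cosine(a, b).score == pytest.approx(
            modified_cosine(a, scaled).score, abs=1e-9
        )

    def test_shift_only_adds_candidates(self, rng):
        shared = rng.uniform(60, 180, size=10)
        for _ in range(100):
            a = random_spectrum(rng, "a", 6, shared)
            b = random_spectrum(rng, "b", 6, shared)
            with_shift = modified_cosine(a, b, allow_shift=True).score
            without = modified_cosine(a, b, allow_shift=False).score
            assert with_shift >= without - 1e-12


def test_agrees_with_matchms_reference_implementation(rng):
    """Independent cross-check against the community modified-cosine scorer."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    scorer = ModifiedCosine(tolerance=0.01)
    shared = rng.uniform(60, 180, size=12)
    checked = 0
    for _ in range(50):
        a = random_spectrum(rng, "a", int(rng.integers(3, 9)), shared)
        b = random_spectrum(rng, "b", int(rng.integers(3, 9)), shared)
        # matchms scores raw intensities, so disable the sqrt weighting
        ours = modified_cosine(a, b, frag_tol=0.01, intensity_power=1.0)
        ma = matchms.Spectrum(
            mz=a.mz, intensities=a.intensity, metadata={"precursor_mz": a.precursor_mz}
        )
        mb = matchms.Spectrum(
            mz=b.mz, intensities=b.intensity, metadata={"precursor_mz": b.precursor_mz}
        )
        score = scorer.pair(ma, mb)
        # matchms pairs greedily, so it can only reach at most our optimum
        assert float(score["score"]) <= ours.score + 1e-9
        if float(score["score"]) > 0:
            checked += 1
    assert checked > 10
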