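"""Build a molecular network from a small analog series.

Three spectra share eight fragment peaks; two are +2 Da analogs of the first,
so the modified cosine pairs their peaks directly and via the precursor
shift.  At the standard thresholds (cosine 0.7, 6 matched peaks) they form
one molecular family, while an unrelated spectrum stays a singleton.
"""

from alkanet import build_network, modified_cosine, molecular_families, spectrum_from_peaks

base = [(60.0 + 18 * i, 1.0 + 0.4 * i) for i in range(8)]
analog = [(mz + (2.0156 if mz > 100 else 0.0), inten) for mz, inten in base]

spectra = [
    spectrum_from_peaks("piperamide_a", 318.13, base),
    spectrum_from_peaks("piperamide_b", 320.15, analog),     # +H2 analog
    spectrum_from_peaks("piperamide_c", 318.13, base),
    spectrum_from_peaks("unrelated", 400.0, [(310.0 + 7 * i, 1.0) for i in range(8)]),
]

res = modified_cosine(spectra[0], spectra[1])
print(f"a vs b: score={res.score:.3f}, matched={res.matched_peaks}, "
      f"shifted pairs={sum(1 for p in res.pairs if p[2])}")

net = build_network(spectra, min_cosine=0.7, min_matched=6)
families, singletons = molecular_families(net)
print(f"molecular families: {[sorted(f) for f in families]}")
print(f"singletons: {singletons}")
# The family groups the three analogs: their spectra match peak-for-peak once
# the precursor mass difference is taken into account; the unrelated spectrum
# shares no fragments and stays alone.
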