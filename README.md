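# alkanet

Computational metabolomics for plant natural-product discovery: feature-based
molecular networking over MS/MS spectra, multi-tier spectral dereplication,
and literature-scale alkaloid-scaffold chemotaxonomy mapped onto a
genus-level angiosperm phylogeny.

The package is aimed at phytochemists and metabolomics researchers who run
untargeted LC–MS/MS on non-model plants and want a reproducible, scriptable
version of the workflow usually spread across hosted services: group unknown
metabolites into molecular families, rule out known compounds before
spending isolation effort, and place the compound classes they find in an
evolutionary context.

## What it computes

**Modified cosine.** Two fragment spectra are compared after square-root
intensity transform and unit-norm scaling. A peak pair (i, j) is a
candidate when |m_i − m_j| ≤ τ (direct) or |m_i − m_j − Δ| ≤ τ (shifted),
where Δ is the precursor mass difference — the shifted channel captures
shared neutral losses between a compound and its analog. The score is

  S(A, B) = max over one-to-one pairings M of Σ_{(i,j)∈M} a_i·b_j,

solved exactly as a maximum-weight assignment problem rather than greedily,
so S is the true optimum (and equals an exhaustive oracle, which the test
suite verifies on 1000 random spectrum pairs).

**Molecular networking.** All spectrum pairs are scored; edges with
S ≥ 0.7 and ≥ 6 matched peaks are kept (τ = 0.01 Da). Connected components
with ≥ 2 nodes are molecular families. Optional mutual top-k and
component-size filters mirror hosted networking services but are off by
default.

**Dereplication.** Exact library matches (precursor within tolerance, plain
cosine) and analog matches (precursor off by up to 100 Da, modified cosine);
a repository-style search against a local indexed library (defaults 0.05 Da
precursor and fragment tolerance, cosine 0.7, ≥ 3 matched peaks, analog off)
aggregates hits into per-species/genus/family counts — an empty result is
the structural-novelty signal. Confirmed annotations propagate one hop along
network edges with modification-delta labels (CH2, H2, O, ...) recomputed
from monoisotopic atomic masses.

**Scaffold chemotaxonomy.** Literature reports (compound SMILES × source
species, e.g. SPARQL query results from Wikidata) are canonicalised,
deduplicated, assigned to named scaffolds by substructure inclusion minus
exclusion patterns, curated against a blocklist of known-bad records, and
collapsed into a genus × scaffold presence matrix with per-cell supporting
references. The matrix is attached to a genus-level Newick phylogeny,
orders without any report are pruned, and one iTOL `DATASET_BINARY` file per
scaffold is exported.

## Worked example

```python
from alkanet import build_network, modified_cosine, molecular_families, spectrum_from_peaks

base = [(60.0 + 18 * i, 1.0 + 0.4 * i) for i in range(8)]
analog = [(mz + (2.0156 if mz > 100 else 0.0), inten) for mz, inten in base]
spectra = [
    spectrum_from_peaks("piperamide_a", 318.13, base),
    spectrum_from_peaks("piperamide_b", 320.15, analog),   # +H2 analog
    spectrum_from_peaks("piperamide_c", 318.13, base),
    spectrum_from_peaks("unrelated", 400.0, [(310.0 + 7 * i, 1.0) for i in range(8)]),
]
res = modified_cosine(spectra[0], spectra[1])
print(f"a vs b: score={res.score:.3f}, matched={res.matched_peaks}")
net = build_network(spectra, min_cosine=0.7, min_matched=6)
families, singletons = molecular_families(net)
print(families, singletons)
```

prints

```
a vs b: score=1.000, matched=8
[['piperamide_a', 'piperamide_b', 'piperamide_c']] ['unrelated']
```

The +H2 analog scores 1.0 because five of its peaks match via the 2.0156 Da
precursor shift and three match directly; all three piperamides collapse
into one molecular family, while the spectrum sharing no fragments stays a
singleton. The `examples/` directory has one narrative script per
capability (networking, dereplication, scaffold mining, phylogeny export,
end-to-end synthetic run), and the same stages are exposed as a CLI:

```bash
alkanet run-all --out-dir demo_out --seed 7
```

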