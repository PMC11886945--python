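# Methods

## Scope and model

alkanet implements the computational core of an untargeted LC–MS/MS
natural-product discovery workflow on plants: spectral preprocessing,
feature-level filtering, modified-cosine molecular networking, multi-tier
dereplication against reference spectra, and chemotaxonomic mapping of
alkaloid scaffolds mined from literature-report tables onto a genus-level
phylogeny. Raw-signal feature detection (XIC construction, smoothing, peak
resolving, isotope filtering, alignment) is upstream of this package and is
expected to have been done in mzmine or equivalent; in-silico structure and
class prediction (SIRIUS/CSI:FingerID/CANOPUS) is consumed as node metadata
when present, never recomputed.

## Spectral model and preprocessing

A spectrum is a feature-linked peak list: strictly ascending m/z, nonnegative
intensities, a positive precursor m/z, retention time in minutes. The MGF
dialect read and written is the mzmine/FBMN exchange dialect (`PEPMASS`,
`RTINSECONDS`, `CHARGE`, `FEATURE_ID`).

Preprocessing removes peaks within 17 Da of the precursor (they carry no
fragment information and can dominate the norm) and keeps the 6 most intense
peaks per sliding 50 Da window. Both values are conventional networking
defaults, configurable and disableable; the workflow's published parameter
set fixes only the downstream tolerances, not these.

Replicate spectra of one feature are merged with a 0.02 Da tolerance by
single-linkage grouping along the sorted m/z axis: merged intensity is the
**sum** of member intensities and merged m/z the **intensity-weighted mean**
of member m/z. This resolves the ambiguity between "sum" and "weighted
average" merge descriptions — each applies to its own quantity. A
consequence of single-linkage is that a chain of peaks each within tolerance
of its neighbour merges into one peak even if its extremes are further
apart; at 0.02 Da on centroided data this is the desired behaviour.

## Modified cosine

Intensities are raised to the 0.5 power (configurable to 1.0 for raw
weighting) and each spectrum is scaled to unit Euclidean norm. Candidate
peak pairs match either directly (|Δm/z| ≤ τ) or shifted by the precursor
mass difference (neutral-loss channel). The reported score is the maximum
over all one-to-one pairings of the sum of weight products, computed exactly
with `scipy.optimize.linear_sum_assignment` on the candidate-weight matrix.
Spectra are small (tens of peaks), so exact assignment costs nothing and
removes the order-dependence of greedy matching. Ties between equally good
pairings are broken toward the pair with the smaller m/z residual via a
bonus of at most 1e-12 per pair — six orders of magnitude below the 1e-9
score tolerance the tests assert, so it can only resolve ties, never change
the optimum. Zero-intensity peaks are dropped before scoring; pair indices
in the result refer to the original peak arrays. A peak participates in at
most one pair, direct or shifted.

## Networking

All pairs are scored with the shift channel on; edges require score ≥ 0.7
and ≥ 6 matched peaks at τ = 0.01 Da. Molecular families are connected
components with ≥ 2 nodes, sorted by size then smallest member id;
singletons are reported separately and are not counted as families. The
mutual top-k filter (default 10) and component-size cap (default 100,
removing globally weakest edges first, ties by node id) exist because hosted
networking services apply such topology filters, but both are **disabled by
default** since only the cosine and matched-peak thresholds are part of the
published parameter set. Replaying deposited data should sweep them.

## Dereplication

Exact mode scores only records whose precursor lies within the precursor
tolerance (default 0.01 Da) using the plain cosine; analog mode scores
records within 100 Da using the modified cosine, so fragment peaks and
neutral losses both contribute. Hits must clear the same 0.7 / 6-peak bar as
network edges. The repository-style search runs the same matching at its
service defaults (0.05 Da precursor and fragment tolerances, cosine 0.7,
≥ 3 matched peaks, analog off) against a local MGF + metadata CSV index and
aggregates matched-record taxa into species/genus/family counts; an empty
aggregate is the novelty signal. Live web services are deliberately not
called: a local index keeps runs reproducible and offline.

Annotation propagation is single-hop: for each unannotated neighbour of a
confirmed node, the edge's precursor delta is looked up in a table of
modification masses (recomputed from monoisotopic atomic masses, so labels
can never drift from their formulas) within 0.01 Da; unmatched deltas are
emitted with an empty label rather than suppressed. Multi-step propagation
is modelled as iterated runs after the user confirms each generation —
automatic transitive chaining silently inflates annotations. Site
localisation within the structure is out of scope; the delta label is a
hypothesis generator, not an identification.

## Scaffold mining

A scaffold query is an inclusion substructure (SMILES/SMARTS), a list of
exclusion substructures, and a curation blocklist. A structure carries a
scaffold iff it contains the inclusion pattern and none of the exclusions
(RDKit subgraph matching; stereochemistry is ignored since the patterns are
achiral). Reports are canonicalised before deduplication, duplicate
(structure, species) pairs merge their references, and unparsable structures
are quarantined to a reject file with counts reported. Curation removes
blocklisted (species, compound) globs and records flagged `lacks-NMR`,
logging every removal with its reason. The presence matrix is a genus-level
OR with per-cell supporting references; per-scaffold summaries count
distinct genera/families/orders, and genera positive for every scaffold are
flagged.

The five shipped scaffold definitions (benzylisoquinoline, aporphine,
piperolactam, piperidine, seco-benzylisoquinoline) are package-authored
patterns with chemically motivated exclusions: quinolizidine and
indolizidine cores veto the piperidine query (lupin/indolizidine alkaloids
contain a piperidine ring), the aporphine tetracycle vetoes the
benzylisoquinoline query (aporphines embed the benzyl-THIQ core but are
counted as their own class), fully aromatic phenanthrenoids veto the
aporphine query, and nitroarenes (aristolochic-acid-type) veto the
piperolactam query. They are data (`data/scaffolds.yaml`), not code, and are
meant to be replaced by the user's own curated query set for production
mining. SPARQL emission is template instantiation only (Wikidata dialect via
the IDSM/Sachem substructure service); executing queries against live
endpoints is out of scope for reproducibility.

## Phylogeny mapping

The reference tree carries one representative species per genus, so mapping
happens on the genus token (first underscore/space-delimited token of the
leaf label), case-sensitively; near-misses differing only in case or
diacritics are reported to aid curation. Orders come from a user-supplied
genus → family → order backbone CSV, never from tree topology, because
Newick internal nodes carry no order labels. Pruning removes all leaves of
orders whose genera are all scaffold-negative and is idempotent. Matrix
genera absent from the tree are returned as an unmapped list; mapped plus
unmapped genera always equal the matrix genera exactly (asserted in tests).
iTOL export writes one `DATASET_BINARY` text file per scaffold (SEPARATOR,
DATASET_LABEL, FIELD_SHAPES, FIELD_LABELS, DATA) plus the pruned Newick,
byte-deterministically.

## Synthetic fixtures

The generator produces, from one seed feeding a single NumPy generator in
fixed draw order:

* **Analog families.** Each family has a base spectrum (uniform fragment
  positions in [50, precursor − 20] Da, log-normal intensities) and members
  that shift the precursor and a per-family *mobile* subset of peaks
  (fraction 0.4) by a modification delta drawn from {H2, CH2, O, C2H4,
  CH2O}. The mobile subset is fixed per family — a modification at a given
  site moves the same fragments in every analog — which keeps every
  member-pair fully matched (direct on immobile peaks, shifted on mobile
  ones); independent per-member subsets would push pairwise matched-peak
  counts below the 6-peak edge threshold at realistic fragment counts.
  Defaults: 6 families of 3–5 members, 10–14 fragments, precursors in
  250–550 Da, multiplicative intensity noise sd 0.05, m/z jitter sd
  0.002 Da, 5 decoy singletons.
* **Separation guarantee.** Fragments are placed by rejection so that no
  peak of a new family or decoy comes within 0.05 Da of any already-placed
  spectrum's peaks in either the direct or the precursor-shifted frame. That
  margin is five times the 0.01 Da networking tolerance plus far more than
  the jitter can bridge, so cross-group modified-cosine scores are exactly
  zero and recovered families equal planted families; within-family scores
  are 1.0 in the noiseless limit (asserted exactly in tests).
* **Report tables.** Positives decorate a scaffold core with random methyl/
  methoxy/hydroxy substituents; decoys are exclusion substructures and
  scaffold-free small molecules. Every candidate is redrawn until its
  rule-based assignment is unambiguously the intended one, so the truth
  table is exact by construction. Species are drawn from the simulated
  tree's genera plus a configurable number of off-tree genera (default 1)
  whose count must reappear as the unmapped-genus list. One decoy report is
  flagged `lacks-NMR` to exercise curation.
* **Feature table.** 3 organs × 3 replicates + 2 blanks; one fifth of
  features are planted blank-contaminated (best blank within 3× of the best
  sample) and another fifth under-replicated (detected in < 3 samples), with
  the survival truth recorded.
* **Tree.** Random bifurcating clades of 4 genera per synthetic order, 24
  genera by default, with a consistent backbone table; branch lengths are
  rounded so Newick bytes are reproducible.

What the generator does **not** emulate: fragmentation chemistry, isotope
envelopes, adducts/in-source fragments, retention-time structure, realistic
taxonomies, or the long-tailed report-count distributions of real literature
data. Passing the synthetic recovery tests therefore demonstrates the
correctness of the matching, thresholding, assignment and mapping logic
under controlled conditions — not performance on real repository data,
where co-eluting isomers, chimeric spectra and taxonomy drift dominate.

## Numerical and design choices

* Score tolerance 1e-9 against the exhaustive oracle; assignment solved
  exactly, no greedy fallback.
* "Detected" means area strictly > 0; the blank rule passes unconditionally
  when a feature is absent from all blanks (infinite fold change).
* Blank fold comparison uses ≥, so a feature at exactly 3× is retained.
* Empty spectra after preprocessing are flagged and excluded from scoring,
  never raised.
* Genus fallback when the report table lacks a genus column: first token of
  the species string (underscore- or space-delimited).
* Problem sizes in tests and the acceptance script (≈30 spectra per seed,
  20 seeds, ≈30 reports per seed) were chosen as the smallest sizes at
  which every planted structure (families, decoys, unmapped genera,
  filter-rule violators) occurs several times per run.

## Known limitations

* The component-size cap removes globally weakest edges, which may not match
  the specific heuristic of any given hosted service; replays should treat
  the topology filters as free parameters.
* Analog scoring uses shifted-peak matching; services that build an explicit
  neutral-loss spectrum can score edge cases differently.
* Scaffold patterns are substructure heuristics: a positional isomer of a
  core (e.g. a differently fused lactam) will not match, and the shipped
  exclusion lists are starting points rather than the curated sets a
  production mining campaign needs.
* Blocklist matching is glob-based on species and compound name (falling
  back to canonical SMILES), so renamed taxa must be listed under each
  spelling.
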