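"""Dereplicate unknowns against a reference library and propagate annotations.

An exact hit identifies one feature; its +CH2 analog is found only by the
neutral-loss-aware analog search.  A repository-style search aggregates hit
taxa, and the confirmed annotation is propagated one hop through the network
with a modification-delta label.
"""

import networkx as nx

from alkanet import (
    LibraryRecord,
    library_search,
    masst_search,
    propagate_delta_annotations,
    spectrum_from_peaks,
)
from alkanet.masses import default_mass_deltas, formula_mass

peaks = [(70.0 + 25 * i, 1.0 + 0.3 * i) for i in range(7)]
library = [
    LibraryRecord(
        "GNPS001", "piperlongumine", spectrum_from_peaks("GNPS001", 318.13, peaks),
        species="Piper longum", genus="Piper", family="Piperaceae",
    )
]

query = spectrum_from_peaks("feat_1", 318.13, peaks)
ch2 = formula_mass("CH2")
analog = spectrum_from_peaks("feat_2", 318.13 + ch2, [(m + ch2, i) for m, i in peaks])

exact = library_search([query], library, mode="exact")
print(f"exact: {exact[0].name} score={exact[0].score:.2f}")
analog_hits = library_search([analog], library, mode="analog")
print(f"analog: {analog_hits[0].name} delta={analog_hits[0].precursor_delta:+.4f} Da "
      f"score={analog_hits[0].score:.2f}")

masst = masst_search(query, library)
print(f"repository search: species={masst.species_counts}, novel={masst.is_novel}")

net = nx.Graph()
net.add_node("feat_1", precursor_mz=318.13)
net.add_node("feat_2", precursor_mz=318.13 + ch2)
net.add_edge("feat_1", "feat_2", score=0.95, matched_peaks=7)
provisional = propagate_delta_annotations(net, exact, default_mass_deltas())
print(provisional[["feature_id", "parent_compound", "precursor_delta", "delta_label"]].to_string(index=False))
# feat_2 is provisionally labeled as a CH2 (methylene) analog of the
# confirmed piperlongumine node - the starting point for standard synthesis
# or manual confirmation, never an automatic identification.
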