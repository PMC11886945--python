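"""One-shot end-to-end run on seeded synthetic fixtures.

Generates spectra with planted analog families, a peak-area table, literature
reports and a genus tree, then runs every stage: filter -> network ->
annotate -> repository search -> scaffold map -> tree -> iTOL.  Equivalent to
`alkanet run-all --out-dir demo_out --seed 7` on the command line.
"""

import json
import tempfile

from alkanet import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as d:
    summary = run_pipeline(PipelineConfig(out_dir=d, seed=7))
    print(json.dumps(summary, indent=2))
# features_retained counts features passing the 3x blank and 3-sample rules;
# molecular_families are the recovered analog groups (one per planted family
# that survives filtering); unmapped_genera counts presence-matrix genera
# absent from the tree (the generator plants exactly one).
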