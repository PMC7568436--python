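"""Faceted search across a collection of BIDS datasets.

Generates a small synthetic corpus, indexes the genetics facets of every
dataset, and searches for studies holding transcriptomic data from brain
samples — the kind of cross-repository query the descriptor exists to make
fast.
"""

import tempfile
from pathlib import Path

from bidsgene import FixtureSpec, QueryFilter, build_index, generate_valid_dataset, search

with tempfile.TemporaryDirectory() as tmp:
    specs = [
        FixtureSpec(name="ukb-style-array", genetic_levels=("genomic",),
                    sample_origins=("blood",),
                    analytic_approaches=("snp genotyping array",), seed=1),
        FixtureSpec(name="brain-expression", genetic_levels=("transcriptomic",),
                    sample_origins=("brain",), tissue_origins=("gray matter",),
                    brain_location="[-30, -22, 10]",
                    analytic_approaches=("rna sequencing",), seed=2),
        FixtureSpec(name="multi-omics", genetic_levels=("genomic", "transcriptomic"),
                    sample_origins=("brain", "saliva"),
                    tissue_origins=("white matter",), seed=3),
    ]
    roots = [generate_valid_dataset(s, Path(tmp) / s.name).root for s in specs]
    entries = build_index(roots)

    filt = QueryFilter(genetic_level=frozenset({"transcriptomic"}),
                       sample_origin=frozenset({"brain"}))
    for hit in search(entries, filt):
        facets = {f: sorted(t) for f, t in hit.facets.items() if t}
        print(hit.name, "->", hit.dataset_url)
        print("   ", facets)
    # Both brain-expression and multi-omics match: facet semantics is AND —
    # every requested term must be present in the dataset's canonical facets.
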