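"""Structural filtering of candidate miRNA hairpins.

Constructs hairpins that pass all criteria or violate exactly one
(score > 10, arm lengths 20-26 nt, randfold p < 0.05, >= 16 paired arm
positions, loop >= 8 nt, exact 2-nt 3' overhangs), applies the filter and
summarizes a small-RNA read set and genomic-context assignment.
"""

import pandas as pd

from plastevo.mirna import (
    FeatureIndex,
    READ_PRIORITY,
    assign_by_priority,
    filter_hairpin,
    small_rna_summary,
)
from plastevo.simulate import generate_hairpins

hairpins, truth = generate_hairpins(n_pass=3, n_fail_per_criterion=1, seed=1)
decisions = pd.DataFrame([filter_hairpin(h).as_dict() for h in hairpins],
                         index=[h.id for h in hairpins])
print(decisions.to_string())
agree = sum(
    filter_hairpin(h).as_dict() == truth.hairpin_truth[h.id] for h in hairpins
)
print(f"\nagreement with constructed truth: {agree}/{len(hairpins)}")

# small-RNA summary: lengths peak at the canonical 22 nt, U-rich 5' ends
import numpy as np

rng = np.random.default_rng(1)
reads = pd.DataFrame(
    {
        "length": rng.choice([21, 22, 23], p=[0.2, 0.6, 0.2], size=5000),
        "first_base": rng.choice(
            ["U", "A", "C", "G"], p=[0.5448, 0.20, 0.13, 0.1252], size=5000
        ),
    }
)
summary = small_rna_summary(reads)
print(
    f"\nread length peak: {summary['peak_length']} nt; "
    f"5' U fraction: {100 * summary['first_base_freq']['U']:.1f}%"
)

# genomic-context priority: a read overlapping both a known miRNA locus and
# an exon is assigned to the known miRNA
index = FeatureIndex(
    [("chr1", 100, 200, "exon"), ("chr1", 150, 180, "known_mirna")],
    priority=READ_PRIORITY,
)
print("\nread at chr1:160-170 ->", assign_by_priority(("chr1", 160, 170), index))
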