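"""Discover a planted bipartite motif in a synthetic sequence set.

Generates 50 sequences of 100 bp, each carrying a TTGACA<8..12>TATAAT
site (95% per-position conservation), runs the entropy-minimizing search
under the mononucleotide (PWM) model and compares the found placements
with the planted truth.
"""

import numpy as np

from bimotif import (
    BipartiteSpec,
    SearchConfig,
    SynthConfig,
    consensus_block,
    generate,
    planted_placements,
    search,
)

spec = BipartiteSpec(l_left=6, l_right=6, gap_min=8, gap_max=12)
config = SynthConfig(
    n_sequences=50,
    seq_length=100,
    spec=spec,
    left_block=consensus_block("TTGACA", 0.95),
    right_block=consensus_block("TATAAT", 0.95),
    seed=1,
)
records, truth, _ = generate(config)

result = search(records, spec, SearchConfig(restarts=20, seed=2))

truth_by_seq = {p.seq_index: p for p in planted_placements(truth, records, spec)}
hits = [
    abs(p.left_start - truth_by_seq[p.seq_index].left_start) <= 1
    for p in result.placements
]
print(f"spec                {spec}")
print(f"final entropy       {result.entropy:.3f} bits")
print(f"converged           {result.converged}")
print(f"recovery (+/-1 bp)  {np.mean(hits):.2f}")
# Entropy is the relative-entropy objective: more negative = more conserved
# motif relative to background.  Recovery is the fraction of sequences whose
# found left-block start lies within 1 bp of the planted one.
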