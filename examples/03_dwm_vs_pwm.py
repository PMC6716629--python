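"""Dinucleotide vs mononucleotide models on a dependency-engineered motif.

The planted blocks come from a first-order letter chain whose per-position
marginals are uniform — a PWM sees nothing — but whose adjacent-pair
mutual information is ~0.71 bits.  The DWM search exploits exactly that
signal.  Recovery is scored as nucleotide-level correlation (nCC) between
predicted and planted block positions.
"""

from bimotif import (
    BipartiteSpec,
    SearchConfig,
    SynthConfig,
    confusion,
    dependency_motif,
    generate,
    ncc,
    placements_to_annotations,
    search,
)

block = dependency_motif(coupling=0.9, width=8)
print(f"analytic adjacent-pair MI of the planted blocks: "
      f"{block.analytic_adjacent_mi:.3f} bits")

for kind in ("di", "mono"):
    spec = BipartiteSpec(8, 8, 10, 10, kind=kind)
    config = SynthConfig(
        n_sequences=100, seq_length=100, spec=spec,
        left_block=block, right_block=block, seed=3,
    )
    records, truth, _ = generate(config)
    result = search(records, spec, SearchConfig(restarts=10, seed=4))
    lengths = {r.id: len(r) for r in records}
    predicted = placements_to_annotations(result.placements, records, spec)
    value = ncc(confusion(truth, predicted, lengths))
    print(f"{'DWM' if kind == 'di' else 'PWM'} recovery nCC: {value:.3f}")
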