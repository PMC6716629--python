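"""Pairwise mutual-information matrix of aligned binding sites.

Base interdependency between site positions is what motivates dinucleotide
models: here MI is computed on sites sampled from a coupled letter chain,
and the adjacent off-diagonal clearly exceeds the distant pairs.
"""

import numpy as np

from bimotif import dependency_motif, mutual_information

block = dependency_motif(coupling=0.8, width=6)
rng = np.random.default_rng(0)
sites = [block.sample(rng) for _ in range(500)]

mi = mutual_information(sites)
print("MI matrix (bits); diagonal = column entropy:")
for row in mi.values:
    print("  " + " ".join(f"{v:5.2f}" for v in row))
adj = np.mean([mi.values[i, i + 1] for i in range(mi.width - 1)])
far = np.mean([mi.values[i, j] for i in range(mi.width) for j in range(mi.width) if j > i + 1])
print(f"mean adjacent-pair MI {adj:.3f} bits vs distant pairs {far:.3f} bits")
print(f"(analytic adjacent MI of the generator: {block.analytic_adjacent_mi:.3f} bits)")
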