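# bimotif

De novo discovery of **bipartite DNA motifs** — transcription-factor
binding sites made of two conserved blocks separated by a variable-length
spacer (written `l_L<[d_min,d_max]>l_R`, e.g. the bacterial promoter
−35/−10 arrangement `6<[11,23]>6`) — in a set of unaligned sequences.

It is aimed at regulatory-genomics users who have a collection of
promoter or ChIP-derived sequences and a rough idea of the block widths
and spacer range, and want the conserved two-block signal plus honest
evaluation machinery around it.

## Method in brief

Every sequence is assigned one candidate site (left-block start and gap
length). The site set is summarised by a **PWM** (per-position base
probabilities) or a **DWM** (per-adjacent-pair dinucleotide
probabilities, capturing nearest-neighbour interdependency), both
pseudo-counted with total mass β = 1:

    p_i(x) = (f_i(x) + β/k) / (N_eff + β),   b(x) = (g(x) + β/k) / (n + β)

and scored by the relative-entropy objective (bits)

    IC = Σ_i Σ_x −p_i(x) · log2( p_i(x) / b(x) )

which is 0 for a background-like motif and decreases with conservation.
The search minimizes IC Gibbs-style: random initial placements, then
greedy per-sequence updates holding all other sequences fixed, sweeps
until the entropy change falls below ε = 1e-8, many random restarts,
best restart wins. Occurrence modes OOPS (one site per sequence), ZOOPS
(zero-or-one, via a log-odds threshold) and ANR (any number of repeats)
are supported.

Evaluation: nucleotide-level correlation coefficient (nCC) and its pooled
"combined" form, sequence-level TPR/FPR for noise detection, and pairwise
mutual-information matrices of aligned sites. A seeded synthetic-data
generator plants bipartite motifs (including dependency-engineered blocks
with uniform marginals that only a DWM can see) for end-to-end testing.

## Worked example

```python
from bimotif import (BipartiteSpec, SearchConfig, SynthConfig,
                     consensus_block, generate, search)

spec = BipartiteSpec(l_left=6, l_right=6, gap_min=8, gap_max=12)
cfg = SynthConfig(n_sequences=50, seq_length=100, spec=spec,
                  left_block=consensus_block("TTGACA", 0.95),
                  right_block=consensus_block("TATAAT", 0.95), seed=1)
records, truth, labels = generate(cfg)
result = search(records, spec, SearchConfig(restarts=20, seed=2))
print(round(result.entropy, 3), result.converged)
```

Running `python examples/01_discover_motif.py` (the same experiment)
prints:

```
spec                6<[8,12]>6
final entropy       -19.496 bits
converged           True
recovery (+/-1 bp)  1.00
```

i.e. the minimum-entropy motif found is 19.5 bits more conserved than the
background and every found left-block start is within 1 bp of the planted
one. The other scripts under `examples/` walk through ZOOPS noise
detection, the DWM-vs-PWM comparison on dependency-engineered motifs, and
mutual-information matrices.

The same workflows are available from the shell:

```
bimotif simulate --config sim.yaml --out-prefix data
bimotif find --input data.fasta --left 6 --right 6 --gap-min 8 --gap-max 12 \
             --matrix dwm --restarts 100 --seed 1 --out-prefix run
bimotif evaluate --known data.truth.tsv --predicted run.placements.tsv \
                 --input data.fasta
bimotif mi --sites sites.txt --out mi.tsv
```

`find` writes a placement report, the probability matrix (for logo
tools), the entropy trace and a manifest capturing every parameter and
input digest.

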