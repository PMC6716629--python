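# Methods

## The model

A bipartite transcription-factor binding site is two conserved blocks of
widths `l_L` and `l_R` separated by a weakly constrained spacer whose
length `d` varies within `[d_min, d_max]`; we write `l_L<[d_min,d_max]>l_R`.
Setting `l_R = 0` (which forces a zero gap) degenerates to an ordinary
one-block motif.

Sites are summarised by one of two column models:

- **PWM (mono)** — one column per block position, 4 symbols (A, C, G, T);
  positions are treated as independent.
- **DWM (di)** — one column per *within-block* adjacent position pair, 16
  symbols (AA..TT); this captures nearest-neighbour interdependency that a
  PWM cannot express. No pair spans the gap or the junction between the
  two blocks: the spacer breaks physical adjacency, so a junction pair is
  not a real dinucleotide. Background pairs likewise require both
  positions to be outside every block.

With a total pseudo-count `β` split evenly over the `k` symbols
(`k` = 4 or 16), the motif and background compositions are

    p_i(x) = (f_i(x) + β/k) / (N_eff + β)
    b(x)   = (g(x)   + β/k) / (n + β)

where `f_i(x)` counts symbol `x` at motif column `i` over the `N_eff`
contributing sites, and `g(x)`/`n` tally symbols at positions not covered
by any block. Gap positions are background: the spacer is explicitly
unconstrained in the model. The background is placement-dependent and is
kept in sync with the current site set rather than frozen from the raw
input. Default `β = 1`.

The objective, in bits, is the negated relative entropy of the motif
columns against the background:

    IC = Σ_i Σ_x −p_i(x) · log2( p_i(x) / b(x) )

IC is 0 when every column matches the background and decreases as columns
concentrate away from it, so *minimizing* IC drives conservation. All
logarithms are base 2 (Shannon / logo convention).

## The search

Each restart initializes every sequence with a uniformly random
(left_start, gap) placement, then repeats greedy sweeps: sequences are
visited in index order (a shuffled order is available behind a flag), the
visited sequence's placement is removed from the counts, every feasible
placement is scored by the total IC it would produce, and the argmin is
committed. Because the incumbent placement is among the candidates, the
entropy trace is non-increasing within a restart. A restart converges
when the entropy change between sweeps is below `ε` (default `1e-8`) or no
placement moved; `max_sweeps` (default 500) is a safety cap. The best of
`restarts` independent restarts (default 100) is returned, ties broken by
the earliest restart.

The per-sequence argmin is evaluated with an exact incremental scheme: the
held-out counts are fixed, so the entropy term of each column depends only
on which symbol the candidate adds, and the background term factorizes
over the candidate's removed background tallies. This reproduces a
from-scratch recomputation to ~1e-15 (property-tested at 1e-9) while
scoring all candidates of a sequence in a handful of vectorized
operations.

Deterministic tie-breaks everywhere: among equal-IC candidates the
smallest left_start wins, then the smallest gap, then the forward strand.
Identical inputs, spec and config (including seed) give bit-identical
results.

### Occurrence modes

- **OOPS** — exactly one site per sequence (the default).
- **ZOOPS** — during each visit the best placement competes with a
  no-occurrence option: the sequence is marked absent when the best
  site's log-odds `Σ_i log2(p_i(x)/b(x))` under the held-out model falls
  below `zoops_threshold` (default 0 bits — the site must beat the
  background). Absent sequences contribute only background counts. If
  fewer than 2 sequences would remain present, the absent option is
  disabled for that visit: an empty motif model is meaningless.
- **ANR** — trained exactly like OOPS, then each sequence is re-scanned
  against the final model, greedily accepting non-overlapping sites (block
  positions may not overlap; gaps may) in descending log-odds order while
  the score stays above the threshold, up to `anr_max_sites` (default 10).
  ANR is a post-training scan, not a joint optimization.

### Strand handling

Forward strand only by default (curated binding-site collections are
pre-oriented). With `both_strands` enabled, reverse-complement placements
compete in the same argmin and the winning strand is reported; coordinates
in reports always map back to the forward strand.

### Ambiguity codes

`N` is accepted in input; any motif or background symbol involving an `N`
contributes uniform fractional mass (1/4 per base, 1/16 per dinucleotide)
to the tallies, keeping every tally total without inventing IUPAC
semantics. Other ambiguity codes are rejected at load time.

## Evaluation statistics

**nCC** is the Matthews correlation over per-nucleotide membership in
known vs predicted sites; the **combined nCC** pools the four tallies
(nTP, nFN, nFP, nTN) over datasets before applying the formula once.
Predicted-site positions are block positions only by default — the gap is
unconstrained in the model, so it is not a prediction — with a
`count_gap_as_site` flag for sensitivity checks. Degenerate tallies (a
zero denominator factor) yield an explicit `None`, never a silent 0.

**TPR/FPR** are sequence-level occurrence-call rates against motif/noise
labels: a "present" call on a motif-free sequence is a false positive.

**Mutual information** between aligned site columns uses plain empirical
frequencies in bits with `0·log 0 := 0`, over *all* position pairs; the
diagonal is the column entropy. No small-sample bias correction is
applied — with few sites the empirical MI is biased upward, which matters
when comparing across site counts, not for the fixtures used here.

## The synthetic generator

`synth.generate` emulates curated binding-site collections: each
motif-bearing sequence receives one planted site (blocks sampled from a
block model, gap from a weight vector over the gap range, offset uniform
among fitting positions) inside background text; a `noise_fraction` of
sequences carries no site. Backgrounds are i.i.d. with arbitrary base
frequencies or first-order Markov; noise sequences come from the same
background model rather than a real genome. Planting overwrites the
background text at block positions, which slightly breaks a Markov
background's chain at block borders.

Block models: `consensus_block(consensus, conservation)` puts
`conservation` probability mass on the consensus base per position
(default 0.95 — a sharp, high-information motif; per-position information
≈ 1.7 bits against a uniform background). `dependency_motif(coupling,
width)` is a first-order letter chain whose next letter stays in the
previous letter's 2-base group ({A,C} vs {G,T}) with probability
`coupling`, else is uniform: marginals are exactly uniform (a PWM sees
nothing) while the adjacent-pair MI is `1 − H_b((1+coupling)/2)` bits —
0 at coupling 0, 1 bit at coupling 1, ≈ 0.71 bits at the 0.9 used in the
dependency experiments.

What the generator does *not* emulate: real genomic composition beyond
first-order structure, overlapping or clustered sites, sequencing error,
or length-correlated site placement. Passing the synthetic benchmarks
therefore demonstrates the search and statistics machinery, not
performance on real promoter collections.

## Experiment sizes

The bundled experiments are desk-scale by design:

- Exhaustive-oracle checks use 3 sequences of length 12 with spec
  `3<[1,2]>3`, where the joint placement space (11³ states) can be
  enumerated outright.
- Planted-recovery curves use `6<[8,12]>6` in 100-bp sequences at
  n ∈ {10, 20, 50, 100, 200}, 20 restarts, medians over 10 seeds.
- Noise-tolerance runs mirror the one-block benchmark shape (a 22-bp
  block in 40-bp sequences) with 100 motif sequences and 25/50/100%
  added noise, ZOOPS at the default 0-bit threshold.
- Dependency experiments use `8<[10]>8` chain blocks at coupling 0.9 vs
  0.0, n = 100.

With these sizes a full search is seconds, not hours; all randomness is
seeded and every number in the README was printed by the bundled code.

## Known limitations

- Greedy per-sequence updates admit coherent *phase-shift* local minima
  (every sequence aligned a base or two off the optimum); restarts are
  the only escape mechanism, so very low restart counts can lock onto a
  shifted solution. No dedicated shift move is implemented.
- Gap lengths are not modeled: all gaps in `[d_min, d_max]` are equally
  acceptable a priori, and no spacer-length penalty is learned.
- ZOOPS presence is a hard log-odds threshold, not a probabilistic
  occurrence prior; the default 0-bit threshold is sensitive to sequence
  length (more background windows raise the best background score).
- Motif widths and the gap range must be user-specified; there is no
  width auto-selection.
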