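"""Bipartite motif search by entropy minimization.

The search follows a Gibbs-sampling strategy for its *structure* — every
restart begins from uniformly random site placements and sequences are
revisited one at a time holding all others fixed — but each per-sequence
update is a deterministic greedy argmin: the held-out sequence's placement
is replaced by the (left_start, gap) pair (plus, under ZOOPS, the
no-occurrence option) that minimizes the total objective
:func:`~bimotif.matrices.information_content`.  Randomness therefore lives
entirely in initialization and restarts, which keeps every run exactly
reproducible from its seed.

A restart converges when the entropy change between consecutive sweeps
drops below ``epsilon`` or no placement moved; the best of ``restarts``
independent restarts (minimum final entropy, earliest index on ties) is
returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import MONO_CONTRIB, N_CODE, PAIR_CONTRIB, padded_pair_codes, pair_codes, reverse_complement
from .matrices import (
    BipartiteSpec,
    ModelState,
    MotifModel,
    Placement,
    block_intervals,
    site_symbol_codes,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "initialize",
    "sweep",
    "run_restart",
    "search",
    "score_candidates",
    "zoops_decision",
    "apply_mode_anr",
]

ABSENT = dict(left_start=-1, gap=0, present=False)


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the search.

    epsilon is the convergence tolerance on the entropy difference between
    sweeps (bits); zoops_threshold is the minimum per-site log-odds (bits)
    for a ZOOPS occurrence to be kept (0 = the site must beat background).
    """

    restarts: int = 100
    seed: int = 0
    epsilon: float = 1e-8
    max_sweeps: int = 500
    zoops_threshold: float = 0.0
    anr_max_sites: int = 10
    beta: float = 1.0
    shuffle_order: bool = False
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class SearchResult:
    placements: list[Placement]
    model: MotifModel
    entropy: float
    entropy_trace: list[float]
    restart_entropies: list[float]
    restart_traces: list[list[float]]
    converged: bool
    spec: BipartiteSpec
    config: SearchConfig
    sequences: list
    best_restart: int = 0


def _seq_label(seq, i: int) -> str:
    return getattr(seq, "id", None) or f"sequence #{i}"


def initialize(
    sequences, spec: BipartiteSpec, rng: np.random.Generator, both_strands: bool = False
) -> list[Placement]:
    """Uniformly random placements: gap from the feasible gap range, then
    left_start uniform among starts where the site fits."""
    placements = []
    for i, seq in enumerate(sequences):
        L = len(seq.seq) if hasattr(seq, "seq") else len(seq)
        feasible = [d for d in spec.gaps() if spec.span(d) <= L]
        if not feasible:
            raise ValueError(
                f"{_seq_label(seq, i)} (length {L}) too short for spec {spec} "
                f"(needs >= {spec.min_span})"
            )
        gap = int(feasible[rng.integers(len(feasible))])
        start = int(rng.integers(L - spec.span(gap) + 1))
        strand = "+" if not both_strands else ("+", "-")[rng.integers(2)]
        placements.append(Placement(seq_index=i, left_start=start, gap=gap, strand=strand))
    return placements


def _sliding(a: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(a, w)


def score_candidates(state: ModelState, i: int, both_strands: bool = False):
    """Objective value of every feasible placement for held-out sequence i.

    Requires sequence i to hold no placement in ``state``.  Returns
    ``(starts, gaps, strands, ics)`` arrays where ``ics[c]`` equals the
    total IC the model would have after committing candidate c.
    """
    spec, beta = state.spec, state.beta
    assert not state.placements[i] and state.cov[i].max() == 0, "sequence must be held out"
    enc = state.enc[i]
    L = enc.size
    k, j = spec.k, spec.n_columns
    lL, lR = spec.l_left, spec.l_right
    has_n = bool((enc == N_CODE).any())

    N0, n0 = state.n_eff, state.n
    Np = N0 + 1 + beta
    p_base = (state.F + beta / k) / Np
    padd = 1.0 / Np
    g0 = state.g

    if not has_n:
        idx = np.arange(k)
        P3 = np.broadcast_to(p_base[:, None, :], (j, k, k)).copy()
        P3[:, idx, idx] += padd
        E = -(P3 * np.log2(P3)).sum(-1)  # E[col, symbol]
        q = p_base.sum(axis=0)
    contrib_site = MONO_CONTRIB if spec.kind == "mono" else PAIR_CONTRIB

    enc_rc = reverse_complement(enc) if both_strands else None
    ppad = padded_pair_codes(enc) if spec.kind == "di" else None

    # candidate (start, gap) grid, identical for both strands
    s_parts, d_parts = [], []
    for d in spec.gaps():
        n_s = L - spec.span(d) + 1
        if n_s >= 1:
            s_parts.append(np.arange(n_s))
            d_parts.append(np.full(n_s, d))
    if not s_parts:
        raise ValueError(f"{_seq_label(None, i)}: no feasible placement")
    s_all = np.concatenate(s_parts)
    d_all = np.concatenate(d_parts)
    span_all = s_all + lL + d_all + lR  # candidate end position

    starts_l, gaps_l, strands_l, ics_l = [], [], [], []
    for strand_ix, strand in enumerate(("+", "-") if both_strands else ("+",)):
        e_s = enc if strand == "+" else enc_rc
        r_all = s_all + lL + d_all  # right block start, strand-oriented
        # --- site symbol windows (strand-oriented) -----------------------
        if spec.kind == "mono":
            parts = [e_s[s_all[:, None] + np.arange(lL)]]
            if lR:
                parts.append(e_s[r_all[:, None] + np.arange(lR)])
            sym = np.concatenate(parts, axis=1).astype(np.intp)
        else:
            pc_s = pair_codes(e_s)
            parts = [pc_s[s_all[:, None] + np.arange(lL - 1)]]
            if lR >= 2:
                parts.append(pc_s[r_all[:, None] + np.arange(lR - 1)])
            sym = np.concatenate(parts, axis=1).astype(np.intp)
        # --- covered forward intervals (ascending order) -----------------
        if strand == "+":
            ivals = [(s_all, lL)] + ([(r_all, lR)] if lR else [])
        else:
            ivals = ([(L - span_all, lR)] if lR else []) + [(L - lL - s_all, lL)]
        # --- background removal ------------------------------------------
        if spec.kind == "mono":
            if strand == "+":
                rem = sym
            else:
                rem = np.concatenate(
                    [enc[a[:, None] + np.arange(w)] for a, w in ivals], axis=1
                ).astype(np.intp)
            R = MONO_CONTRIB[rem].sum(axis=1)
        else:
            R = sum(
                PAIR_CONTRIB[ppad[a[:, None] + np.arange(w + 1)]].sum(axis=1)
                for a, w in ivals
            )
            if lR and spec.gap_min == 0:
                # contiguous blocks (gap 0) double-count the junction pair
                zero = d_all == 0
                if zero.any():
                    R[zero] -= PAIR_CONTRIB[ppad[ivals[1][0][zero]]]
        n_rem = R.sum(axis=1)
        b = (g0[None, :] - R + beta / k) / (n0 - n_rem + beta)[:, None]
        logb = np.log2(b)
        # --- objective ---------------------------------------------------
        if not has_n:
            ent = E[np.arange(j)[None, :], sym].sum(axis=1)
            ic = ent + logb @ q + padd * np.take_along_axis(logb, sym, axis=1).sum(axis=1)
        else:
            C3 = contrib_site[sym]  # (n_c, j, k)
            p = p_base[None, :, :] + padd * C3
            ic = -(p * np.log2(p)).sum(axis=(1, 2)) + (p * logb[:, None, :]).sum(
                axis=(1, 2)
            )
        starts_l.append(s_all)
        gaps_l.append(d_all)
        strands_l.append(np.full(s_all.size, strand_ix))
        ics_l.append(ic)
    return (
        np.concatenate(starts_l),
        np.concatenate(gaps_l),
        np.concatenate(strands_l),
        np.concatenate(ics_l),
    )


def _best_candidate(starts, gaps, strands, ics) -> tuple[int, int, str, float]:
    """Argmin with deterministic tie-break: smallest left_start, then gap."""
    m = ics.min()
    tie = np.nonzero(ics == m)[0]
    order = np.lexsort((strands[tie], gaps[tie], starts[tie]))
    c = tie[order[0]]
    return int(starts[c]), int(gaps[c]), "+-"[int(strands[c])], float(ics[c])


def _held_out_log_odds(state: ModelState, p: Placement) -> float:
    """Log-odds of a candidate site under the model of the *other* sequences."""
    spec, beta, k = state.spec, state.beta, state.spec.k
    probs = (state.F + beta / k) / (state.n_eff + beta)
    bg = (state.g + beta / k) / (state.n + beta)
    codes = site_symbol_codes(state.enc[p.seq_index], p, spec)
    contrib = (MONO_CONTRIB if spec.kind == "mono" else PAIR_CONTRIB)[codes]
    return float(np.log2((contrib * probs).sum(1) / (contrib @ bg)).sum())


def zoops_decision(log_odds: float, threshold: float, n_present_others: float) -> bool:
    """True = keep the occurrence.  The absent option is disabled when fewer
    than 2 sequences would remain present (an empty model is meaningless)."""
    if n_present_others < 2:
        return True
    return log_odds >= threshold


def sweep(
    state: ModelState, config: SearchConfig, rng: np.random.Generator | None = None
) -> tuple[float, bool]:
    """One greedy pass over all sequences in index order (or shuffled).

    Each visited sequence's placement is removed, every feasible placement
    is scored, and the argmin is committed; under ZOOPS the no-occurrence
    option competes via the log-odds threshold.  Returns the entropy after
    the pass and whether any placement changed.
    """
    n = len(state.enc)
    order = np.arange(n)
    if config.shuffle_order:
        if rng is None:
            raise ValueError("shuffle_order requires an RNG")
        rng.shuffle(order)
    changed = False
    zoops = state.spec.mode == "zoops"
    for i in order:
        i = int(i)
        old = state.clear_sequence(i)
        old_p = old[0] if old else None
        s, d, strand, _ = _best_candidate(
            *score_candidates(state, i, both_strands=config.both_strands)
        )
        cand = Placement(seq_index=i, left_start=s, gap=d, strand=strand)
        if zoops and not zoops_decision(
            _held_out_log_odds(state, cand), config.zoops_threshold, state.n_eff
        ):
            cand = Placement(seq_index=i, **ABSENT)
        state.add(cand)
        if old_p != cand:
            changed = True
    return state.ic(), changed


def run_restart(
    sequences, spec: BipartiteSpec, config: SearchConfig, rng: np.random.Generator
) -> SearchResult:
    """One restart: random initialization, then sweeps to convergence."""
    state = ModelState(sequences, spec, beta=config.beta)
    for p in initialize(sequences, spec, rng, both_strands=config.both_strands):
        state.add(p)
    trace = [state.ic()]
    converged = False
    for _ in range(config.max_sweeps):
        entropy, changed = sweep(state, config, rng)
        trace.append(entropy)
        if not changed or abs(trace[-1] - trace[-2]) < config.epsilon:
            converged = True
            break
    return SearchResult(
        placements=state.all_placements(),
        model=state.model(),
        entropy=trace[-1],
        entropy_trace=trace,
        restart_entropies=[trace[-1]],
        restart_traces=[trace],
        converged=converged,
        spec=spec,
        config=config,
        sequences=list(sequences),
    )


def search(sequences, spec: BipartiteSpec, config: SearchConfig) -> SearchResult:
    """Full search: independent seeded restarts; the minimum-entropy restart
    wins (earliest index on ties).  Under ANR the winning model is used for
    a final multi-occurrence scan of every sequence."""
    children = np.random.SeedSequence(config.seed).spawn(config.restarts)
    best: SearchResult | None = None
    entropies: list[float] = []
    traces: list[list[float]] = []
    for r in range(config.restarts):
        res = run_restart(sequences, spec, config, np.random.default_rng(children[r]))
        entropies.append(res.entropy)
        traces.append(res.entropy_trace)
        if best is None or res.entropy < best.entropy:
            best = res
            best.best_restart = r
    assert best is not None
    best.restart_entropies = entropies
    best.restart_traces = traces
    if spec.mode == "anr":
        best.placements = [
            p
            for i, seq in enumerate(sequences)
            for p in apply_mode_anr(i, seq, best.model, spec, config)
        ]
    return best


def _enumerate_log_odds(enc: np.ndarray, model: MotifModel, spec: BipartiteSpec,
                        both_strands: bool):
    """(starts, gaps, strands, scores) of every candidate site vs a fixed model."""
    contrib = MONO_CONTRIB if spec.kind == "mono" else PAIR_CONTRIB
    L = enc.size
    enc_rc = reverse_complement(enc) if both_strands else None
    out = [[], [], [], []]
    for strand_ix, strand in enumerate(("+", "-") if both_strands else ("+",)):
        e_s = enc if strand == "+" else enc_rc
        pc_s = pair_codes(e_s) if spec.kind == "di" else None
        for d in spec.gaps():
            span = spec.span(d)
            n_s = L - span + 1
            if n_s < 1:
                continue
            if spec.kind == "mono":
                parts = [_sliding(e_s, spec.l_left)[:n_s]]
                if spec.l_right:
                    parts.append(
                        _sliding(e_s, spec.l_right)[spec.l_left + d : spec.l_left + d + n_s]
                    )
            else:
                parts = [_sliding(pc_s, spec.l_left - 1)[:n_s]]
                if spec.l_right >= 2:
                    parts.append(
                        _sliding(pc_s, spec.l_right - 1)[
                            spec.l_left + d : spec.l_left + d + n_s
                        ]
                    )
            sym = np.concatenate(parts, axis=1).astype(np.intp)
            C3 = contrib[sym]
            num = (C3 * model.probs[None, :, :]).sum(-1)
            den = C3 @ model.background
            scores = np.log2(num / den).sum(axis=1)
            out[0].append(np.arange(n_s))
            out[1].append(np.full(n_s, d))
            out[2].append(np.full(n_s, strand_ix))
            out[3].append(scores)
    return tuple(np.concatenate(x) for x in out)


def apply_mode_anr(
    seq_index: int, seq, model: MotifModel, spec: BipartiteSpec, config: SearchConfig
) -> list[Placement]:
    """Final ANR scan of one sequence against the trained model.

    Candidates are accepted in descending log-odds order while the score
    stays >= the threshold, block positions do not overlap an accepted
    site (gaps may overlap), and at most ``anr_max_sites`` are kept.
    """
    from .matrices import _as_encoded

    enc = _as_encoded(seq)
    starts, gaps, strands, scores = _enumerate_log_odds(
        enc, model, spec, config.both_strands
    )
    order = np.lexsort((strands, gaps, starts, -scores))
    occupied = np.zeros(enc.size, dtype=bool)
    kept: list[Placement] = []
    for c in order:
        if scores[c] < config.zoops_threshold or len(kept) >= config.anr_max_sites:
            break
        p = Placement(
            seq_index=seq_index,
            left_start=int(starts[c]),
            gap=int(gaps[c]),
            strand="+-"[int(strands[c])],
        )
        ivals = block_intervals(p, spec, enc.size)
        if any(occupied[a:b].any() for a, b in ivals):
            continue
        for a, b in ivals:
            occupied[a:b] = True
        kept.append(p)
    kept.sort(key=lambda p: (p.left_start, p.gap))
    return kept
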