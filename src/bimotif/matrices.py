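"""Motif probability models and the entropy objective.

A bipartite motif is two conserved blocks of widths ``l_left`` and
``l_right`` separated by an unconstrained spacer of ``gap_min``..``gap_max``
bases, written ``l_L<[d_min,d_max]>l_R``.  Sites are summarised either by a
mononucleotide model (PWM, one column per block position, 4 symbols) or a
dinucleotide model (DWM, one column per *within-block* adjacent pair, 16
symbols).  Gap positions are never motif columns; for the DWM no pair spans
the gap or the junction between the concatenated blocks.

With pseudo-count ``beta`` split evenly over the ``k`` symbols, the motif
and background compositions are

    p_i(x) = (f_i(x) + beta/k) / (N_eff + beta)
    b(x)   = (g(x)   + beta/k) / (n + beta)

where ``f_i`` counts symbol occurrences at motif column ``i`` over the
``N_eff`` contributing sites, and ``g``/``n`` tally the symbols *not*
covered by any motif block (gaps included).  The objective the search
minimizes is the (negated) relative entropy of the motif against that
background, in bits:

    IC = sum_i sum_x  -p_i(x) * log2( p_i(x) / b(x) )

IC is 0 when every column equals the background and becomes more negative
as columns concentrate away from it, so minimization drives conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alphabet import (
    BASES,
    DINUCLEOTIDES,
    MONO_CONTRIB,
    PAIR_CONTRIB,
    encode,
    pair_codes,
    reverse_complement,
)

__all__ = [
    "BipartiteSpec",
    "Placement",
    "CountMatrix",
    "BackgroundCounts",
    "MotifModel",
    "ModelState",
    "EmptyModelError",
    "count_sites",
    "background_counts",
    "to_model",
    "information_content",
    "site_log_odds",
    "delta_ic_remove_add",
    "reference_ic",
    "export_matrix",
    "read_matrix",
]


class EmptyModelError(ValueError):
    """Raised when a model would be built from zero sites with zero beta."""


@dataclass(frozen=True)
class BipartiteSpec:
    """Search problem definition: block widths, gap range, model kind, mode."""

    l_left: int
    l_right: int
    gap_min: int
    gap_max: int
    kind: str = "mono"  # "mono" (PWM) or "di" (DWM)
    mode: str = "oops"  # "oops" | "zoops" | "anr"

    def __post_init__(self) -> None:
        if self.l_left < 1:
            raise ValueError("l_left must be >= 1")
        if self.l_right < 0:
            raise ValueError("l_right must be >= 0")
        if self.l_right == 0 and not (self.gap_min == 0 and self.gap_max == 0):
            raise ValueError("one-block spec (l_right=0) requires gap_min=gap_max=0")
        if not (0 <= self.gap_min <= self.gap_max):
            raise ValueError("need 0 <= gap_min <= gap_max")
        if self.kind not in ("mono", "di"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.mode not in ("oops", "zoops", "anr"):
            raise ValueError(f"unknown occurrence mode {self.mode!r}")
        if self.kind == "di":
            if self.l_left < 2 or (self.l_right not in (0,) and self.l_right < 2):
                raise ValueError("di kind needs every block to hold >= 1 dinucleotide")

    @property
    def k(self) -> int:
        return 4 if self.kind == "mono" else 16

    @property
    def block_width(self) -> int:
        return self.l_left + self.l_right

    @property
    def n_columns(self) -> int:
        if self.kind == "mono":
            return self.l_left + self.l_right
        return (self.l_left - 1) + max(self.l_right - 1, 0)

    def span(self, gap: int) -> int:
        return self.l_left + gap + self.l_right

    @property
    def min_span(self) -> int:
        return self.span(self.gap_min)

    def gaps(self) -> range:
        return range(self.gap_min, self.gap_max + 1)

    def __str__(self) -> str:
        if self.l_right == 0:
            return f"{self.l_left}<[0]>0"
        if self.gap_min == self.gap_max:
            return f"{self.l_left}<[{self.gap_min}]>{self.l_right}"
        return f"{self.l_left}<[{self.gap_min},{self.gap_max}]>{self.l_right}"


@dataclass(frozen=True)
class Placement:
    """One motif occurrence: (left block start, gap length) in one sequence.

    Coordinates are 0-based half-open on the forward strand for ``strand
    '+'``; for ``strand '-'`` the offsets refer to the reverse-complemented
    sequence and map back to forward intervals via the sequence length.
    ``present=False`` marks a ZOOPS non-occurrence.
    """

    seq_index: int
    left_start: int
    gap: int
    present: bool = True
    strand: str = "+"


def block_intervals(p: Placement, spec: BipartiteSpec, seq_len: int) -> list[tuple[int, int]]:
    """Forward-strand half-open intervals covered by the placement's blocks."""
    span = spec.span(p.gap)
    if p.left_start < 0 or p.left_start + span > seq_len:
        raise ValueError(
            f"placement at {p.left_start} (span {span}) exceeds sequence of length {seq_len}"
        )
    if not (spec.gap_min <= p.gap <= spec.gap_max):
        raise ValueError(f"gap {p.gap} outside [{spec.gap_min}, {spec.gap_max}]")
    s = p.left_start
    if p.strand == "+":
        ivals = [(s, s + spec.l_left)]
        if spec.l_right:
            r = s + spec.l_left + p.gap
            ivals.append((r, r + spec.l_right))
        return ivals
    # reverse strand: map reverse-complement coordinates back to forward
    lo = seq_len - s - span
    ivals = [(seq_len - s - spec.l_left, seq_len - s)]
    if spec.l_right:
        ivals.insert(0, (lo, lo + spec.l_right))
    return ivals


def _as_encoded(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    if hasattr(seq, "seq"):
        return encode(str(seq.seq))
    return encode(str(seq))


def site_symbol_codes(enc: np.ndarray, p: Placement, spec: BipartiteSpec) -> np.ndarray:
    """Per-column symbol codes of the site a placement selects.

    ``enc`` is the forward-strand encoding; reverse-strand placements read
    from the reverse complement.
    """
    e = enc if p.strand == "+" else reverse_complement(enc)
    s = p.left_start
    r = s + spec.l_left + p.gap
    left = e[s : s + spec.l_left]
    right = e[r : r + spec.l_right]
    if spec.kind == "mono":
        return np.concatenate([left, right]).astype(np.int16)
    parts = [pair_codes(left)]
    if spec.l_right >= 2:
        parts.append(pair_codes(right))
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int16)


@dataclass
class CountMatrix:
    kind: str
    counts: np.ndarray  # (n_columns, k)
    n_eff: float
    spec: BipartiteSpec | None = None


@dataclass
class BackgroundCounts:
    g: np.ndarray  # (k,)
    n: float


@dataclass
class MotifModel:
    kind: str
    probs: np.ndarray  # (n_columns, k)
    background: np.ndarray  # (k,)
    beta: float
    spec: BipartiteSpec | None = None

    @property
    def n_columns(self) -> int:
        return self.probs.shape[0]


def _contrib(kind: str) -> np.ndarray:
    return MONO_CONTRIB if kind == "mono" else PAIR_CONTRIB


def count_sites(
    sequences: Sequence, placements: Iterable[Placement], spec: BipartiteSpec
) -> CountMatrix:
    """Tally symbol counts at each motif column over the present placements."""
    encs = [_as_encoded(s) for s in sequences]
    counts = np.zeros((spec.n_columns, spec.k))
    contrib = _contrib(spec.kind)
    n_eff = 0
    for p in placements:
        if not p.present:
            continue
        block_intervals(p, spec, encs[p.seq_index].size)  # bounds check
        codes = site_symbol_codes(encs[p.seq_index], p, spec)
        counts += contrib[codes]
        n_eff += 1
    return CountMatrix(kind=spec.kind, counts=counts, n_eff=float(n_eff), spec=spec)


def _coverage(encs: list[np.ndarray], placements: Iterable[Placement], spec: BipartiteSpec):
    cov = [np.zeros(e.size, dtype=np.int32) for e in encs]
    for p in placements:
        if not p.present:
            continue
        for a, b in block_intervals(p, spec, encs[p.seq_index].size):
            cov[p.seq_index][a:b] += 1
    return cov


def _seq_background(enc: np.ndarray, cov: np.ndarray, kind: str) -> tuple[np.ndarray, float]:
    """Background tallies of one sequence given its block-coverage array."""
    free = cov == 0
    if kind == "mono":
        idx = enc[free]
        g = MONO_CONTRIB[idx].sum(axis=0) if idx.size else np.zeros(4)
        return g, float(idx.size)
    codes = pair_codes(enc)
    mask = free[:-1] & free[1:]
    sel = codes[mask]
    g = PAIR_CONTRIB[sel].sum(axis=0) if sel.size else np.zeros(16)
    return g, float(sel.size)


def background_counts(
    sequences: Sequence, placements: Iterable[Placement], spec: BipartiteSpec
) -> BackgroundCounts:
    """Tally symbols not covered by any block (gap positions are background).

    For the dinucleotide kind a pair is background only when *both* of its
    positions are uncovered.
    """
    encs = [_as_encoded(s) for s in sequences]
    cov = _coverage(encs, placements, spec)
    g = np.zeros(spec.k)
    n = 0.0
    for e, c in zip(encs, cov):
        gi, ni = _seq_background(e, c, spec.kind)
        g += gi
        n += ni
    return BackgroundCounts(g=g, n=n)


def to_model(counts: CountMatrix, bg: BackgroundCounts, beta: float = 1.0) -> MotifModel:
    """Pseudo-counted probabilities p_i(x) and background b(x)."""
    k = counts.counts.shape[1]
    if counts.n_eff + beta <= 0 or bg.n + beta <= 0:
        raise EmptyModelError("empty model: no sites and no pseudo-count")
    probs = (counts.counts + beta / k) / (counts.n_eff + beta)
    background = (bg.g + beta / k) / (bg.n + beta)
    return MotifModel(
        kind=counts.kind, probs=probs, background=background, beta=beta, spec=counts.spec
    )


def _ic_from_arrays(probs: np.ndarray, background: np.ndarray) -> float:
    if np.any((probs > 0) & (background <= 0)):
        raise ValueError("background probability 0 where motif probability > 0")
    mask = probs > 0
    safe_p = np.where(mask, probs, 1.0)
    ratio = np.log2(safe_p / np.where(mask, background, 1.0))
    return float((-safe_p * ratio * mask).sum())


def information_content(model: MotifModel) -> float:
    """The entropy objective in bits (0 at background; negative when conserved)."""
    return _ic_from_arrays(model.probs, model.background)


def site_log_odds(model: MotifModel, seq, left_start: int, gap: int,
                  spec: BipartiteSpec | None = None, strand: str = "+") -> float:
    """Sum over motif columns of log2(p_i(x)/b(x)) for the site at (left_start, gap)."""
    spec = spec or model.spec
    if spec is None:
        raise ValueError("spec required (not carried by this model)")
    enc = _as_encoded(seq)
    p = Placement(seq_index=0, left_start=left_start, gap=gap, strand=strand)
    block_intervals(p, spec, enc.size)  # bounds check
    codes = site_symbol_codes(enc, p, spec)
    contrib = _contrib(spec.kind)[codes]  # (j, k)
    num = (contrib * model.probs).sum(axis=1)
    den = contrib @ model.background
    return float(np.log2(num / den).sum())


def reference_ic(
    sequences: Sequence, placements: Iterable[Placement], spec: BipartiteSpec, beta: float = 1.0
) -> float:
    """From-scratch objective evaluation (counts rebuilt from the sequences)."""
    placements = list(placements)
    cm = count_sites(sequences, placements, spec)
    bg = background_counts(sequences, placements, spec)
    return information_content(to_model(cm, bg, beta=beta))


class ModelState:
    """Incrementally-maintained counts for a placement set.

    Holds the motif count matrix, the background tallies and per-sequence
    block-coverage arrays so that adding or removing one placement is O(L)
    instead of a full re-tally, while :meth:`ic` stays exactly the objective
    of the current placement set.
    """

    def __init__(self, sequences: Sequence, spec: BipartiteSpec, beta: float = 1.0):
        self.spec = spec
        self.beta = beta
        self.enc = [_as_encoded(s) for s in sequences]
        self.cov = [np.zeros(e.size, dtype=np.int32) for e in self.enc]
        self.F = np.zeros((spec.n_columns, spec.k))
        self.n_eff = 0.0
        self.g = np.zeros(spec.k)
        self.n = 0.0
        self.placements: dict[int, list[Placement]] = {i: [] for i in range(len(self.enc))}
        for e, c in zip(self.enc, self.cov):
            gi, ni = _seq_background(e, c, spec.kind)
            self.g += gi
            self.n += ni
        self._contrib = _contrib(spec.kind)

    @classmethod
    def from_placements(
        cls, sequences: Sequence, placements: Iterable[Placement],
        spec: BipartiteSpec, beta: float = 1.0,
    ) -> "ModelState":
        state = cls(sequences, spec, beta=beta)
        for p in placements:
            if p.present:
                state.add(p)
            else:
                state.placements[p.seq_index].append(p)
        return state

    def _update_background(self, i: int, ivals, sign: int) -> None:
        g_old, n_old = _seq_background(self.enc[i], self.cov[i], self.spec.kind)
        for a, b in ivals:
            self.cov[i][a:b] += sign
        g_new, n_new = _seq_background(self.enc[i], self.cov[i], self.spec.kind)
        self.g += g_new - g_old
        self.n += n_new - n_old

    def add(self, p: Placement) -> None:
        if not p.present:
            self.placements[p.seq_index].append(p)
            return
        i = p.seq_index
        ivals = block_intervals(p, self.spec, self.enc[i].size)
        codes = site_symbol_codes(self.enc[i], p, self.spec)
        self.F += self._contrib[codes]
        self.n_eff += 1
        self._update_background(i, ivals, +1)
        self.placements[i].append(p)

    def remove(self, p: Placement) -> None:
        self.placements[p.seq_index].remove(p)
        if not p.present:
            return
        i = p.seq_index
        ivals = block_intervals(p, self.spec, self.enc[i].size)
        codes = site_symbol_codes(self.enc[i], p, self.spec)
        self.F -= self._contrib[codes]
        self.n_eff -= 1
        self._update_background(i, ivals, -1)

    def clear_sequence(self, i: int) -> list[Placement]:
        """Remove (and return) every placement recorded for sequence i."""
        current = list(self.placements[i])
        for p in current:
            self.remove(p)
        return current

    def all_placements(self) -> list[Placement]:
        out: list[Placement] = []
        for i in sorted(self.placements):
            out.extend(self.placements[i])
        return out

    def model(self) -> MotifModel:
        cm = CountMatrix(self.spec.kind, self.F.copy(), self.n_eff, spec=self.spec)
        bg = BackgroundCounts(self.g.copy(), self.n)
        return to_model(cm, bg, beta=self.beta)

    def ic(self) -> float:
        return information_content(self.model())

    def held_out_distributions(self) -> tuple[np.ndarray, np.ndarray]:
        """(p, b) of the current counts — used to score a candidate site."""
        m = self.model()
        return m.probs, m.background


def delta_ic_remove_add(
    state: ModelState, old: Placement | None, new: Placement | None
) -> float:
    """Apply a placement swap to ``state`` and return IC(after) - IC(before).

    Either side may be ``None`` (pure removal / pure addition).  The counts
    are updated incrementally; the returned change matches a from-scratch
    recomputation to well below 1e-9.
    """
    before = state.ic()
    if old is not None:
        state.remove(old)
    if new is not None:
        state.add(new)
    return state.ic() - before


# ---------------------------------------------------------------------------
# matrix export / import


def _column_labels(spec: BipartiteSpec | None, n_columns: int, kind: str) -> list[str]:
    if spec is None:
        return [f"p{i + 1}" for i in range(n_columns)]
    if kind == "mono":
        return [f"L{i + 1}" for i in range(spec.l_left)] + [
            f"R{i + 1}" for i in range(spec.l_right)
        ]
    labels = [f"L{i + 1}:{i + 2}" for i in range(spec.l_left - 1)]
    if spec.l_right >= 2:
        labels += [f"R{i + 1}:{i + 2}" for i in range(spec.l_right - 1)]
    return labels


def export_matrix(model: MotifModel, path) -> None:
    """Write the probability matrix as TSV: rows = symbols, columns = positions.

    The header carries the model kind and, when the block split is known,
    labels columns ``L*``/``R*`` so the left/right boundary is explicit.
    Entries use full precision and round-trip exactly through read_matrix.
    """
    symbols = list(BASES) if model.kind == "mono" else list(DINUCLEOTIDES)
    labels = _column_labels(model.spec, model.n_columns, model.kind)
    with open(path, "w") as fh:
        meta = f"# kind={model.kind}\tbeta={model.beta:.17g}"
        if model.spec is not None:
            meta += f"\tleft={model.spec.l_left}\tright={model.spec.l_right}"
            meta += f"\tgap_min={model.spec.gap_min}\tgap_max={model.spec.gap_max}"
        fh.write(meta + "\n")
        fh.write("symbol\t" + "\t".join(labels) + "\tbackground\n")
        for r, sym in enumerate(symbols):
            row = "\t".join(f"{v:.17g}" for v in model.probs[:, r])
            fh.write(f"{sym}\t{row}\t{model.background[r]:.17g}\n")


def read_matrix(path) -> MotifModel:
    """Inverse of :func:`export_matrix`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    meta: dict[str, str] = {}
    if lines and lines[0].startswith("#"):
        for tok in lines.pop(0).lstrip("# ").split("\t"):
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
    header = lines.pop(0).split("\t")
    n_cols = len(header) - 2  # symbol column + background column
    kind = meta.get("kind", "mono" if len(lines) == 4 else "di")
    probs = np.zeros((n_cols, 4 if kind == "mono" else 16))
    background = np.zeros(probs.shape[1])
    symbols = list(BASES) if kind == "mono" else list(DINUCLEOTIDES)
    index = {s: r for r, s in enumerate(symbols)}
    for ln in lines:
        parts = ln.split("\t")
        r = index[parts[0]]
        probs[:, r] = [float(v) for v in parts[1:-1]]
        background[r] = float(parts[-1])
    spec = None
    if "left" in meta:
        spec = BipartiteSpec(
            l_left=int(meta["left"]), l_right=int(meta["right"]),
            gap_min=int(meta.get("gap_min", 0)), gap_max=int(meta.get("gap_max", 0)),
            kind=kind,
        )
    return MotifModel(
        kind=kind, probs=probs, background=background,
        beta=float(meta.get("beta", 1.0)), spec=spec,
    )
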