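"""Synthetic datasets with planted bipartite motifs.

The generator emulates the structure of curated binding-site collections:
each motif-bearing sequence carries exactly one planted site — two blocks
drawn from a block model, separated by a gap drawn from a weight vector
over the spec's gap range — embedded at a uniform random offset in
background text (i.i.d. or first-order Markov).  An optional fraction of
sequences carries no site at all ("noise"), mirroring noise-spiking
benchmarks.  Ground-truth block intervals and per-sequence motif/noise
labels are returned alongside the sequences, so recovery and detection
statistics can be computed exactly.

Two block-model families are provided: independent per-position
probabilities (optionally built from a consensus string with a tunable
conservation level), and first-order letter chains with uniform marginals
whose adjacent-pair mutual information grows with a coupling parameter —
the latter is invisible to a mononucleotide model by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import BASES
from .io_seq import SequenceRecord, SiteAnnotation
from .matrices import BipartiteSpec, Placement

__all__ = [
    "PwmBlock",
    "ChainBlock",
    "consensus_block",
    "dependency_motif",
    "Background",
    "SynthConfig",
    "generate",
    "planted_placements",
]


@dataclass(frozen=True)
class PwmBlock:
    """Independent per-position base probabilities, shape (width, 4)."""

    probs: tuple  # nested tuples for hashability; rows sum to 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("PwmBlock needs a (width, 4) probability table")
        if not np.allclose(arr.sum(axis=1), 1.0):
            raise ValueError("block probability rows must sum to 1")

    @property
    def width(self) -> int:
        return len(self.probs)

    def sample(self, rng: np.random.Generator) -> str:
        arr = np.asarray(self.probs)
        return "".join(BASES[rng.choice(4, p=row)] for row in arr)


def consensus_block(consensus: str, conservation: float = 0.95) -> PwmBlock:
    """Block model putting ``conservation`` mass on each consensus base and
    splitting the rest evenly over the other three."""
    if not 0.25 <= conservation <= 1.0:
        raise ValueError("conservation must be in [0.25, 1]")
    rows = []
    off = (1.0 - conservation) / 3.0
    for ch in consensus.upper():
        if ch not in BASES:
            raise ValueError(f"consensus base {ch!r} not in ACGT")
        row = [off] * 4
        row[BASES.index(ch)] = conservation
        rows.append(tuple(row))
    return PwmBlock(probs=tuple(rows))


# base group used by the coupled chain: {A, C} vs {G, T}
_GROUP = np.array([0, 0, 1, 1])
_GROUP_MEMBERS = (np.array([0, 1]), np.array([2, 3]))


@dataclass(frozen=True)
class ChainBlock:
    """First-order letter chain with uniform per-position marginals.

    The next letter stays in the previous letter's 2-base group
    ({A,C} vs {G,T}) with probability ``coupling`` (then uniform within the
    group) and is otherwise uniform over all 4 bases.  Marginals stay
    uniform by symmetry, so a mononucleotide model sees nothing, while the
    adjacent-pair distribution carries
    MI = 1 - H_b((1 + coupling)/2) bits (H_b = binary entropy).
    """

    width: int
    coupling: float

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("ChainBlock needs width >= 2")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")

    @property
    def analytic_adjacent_mi(self) -> float:
        """Exact MI (bits) between adjacent positions of the chain."""
        p_same = (1.0 + self.coupling) / 2.0
        if p_same in (0.0, 1.0):
            hb = 0.0
        else:
            hb = -(p_same * np.log2(p_same) + (1 - p_same) * np.log2(1 - p_same))
        return 1.0 - hb

    def pair_distribution(self) -> np.ndarray:
        """Joint (4, 4) distribution of an adjacent letter pair."""
        joint = np.full((4, 4), (1 - self.coupling) / 16.0)
        for x in range(4):
            joint[x, _GROUP_MEMBERS[_GROUP[x]]] += self.coupling / 8.0
        return joint

    def sample(self, rng: np.random.Generator) -> str:
        letters = [int(rng.integers(4))]
        for _ in range(self.width - 1):
            if rng.random() < self.coupling:
                prev_group = _GROUP[letters[-1]]
                letters.append(int(rng.choice(_GROUP_MEMBERS[prev_group])))
            else:
                letters.append(int(rng.integers(4)))
        return "".join(BASES[i] for i in letters)


def dependency_motif(coupling: float, width: int) -> ChainBlock:
    """Block model with engineered nearest-neighbour dependency.

    coupling = 0 gives i.i.d. uniform letters; coupling = 1 couples each
    letter deterministically to its predecessor's group (adjacent MI = 1
    bit).
    """
    return ChainBlock(width=width, coupling=coupling)


@dataclass(frozen=True)
class Background:
    """Background text model: i.i.d. base frequencies or a first-order chain."""

    kind: str = "iid"  # "iid" | "markov1"
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    transition: tuple | None = None  # (4, 4) rows sum to 1, markov1 only

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or not np.isclose(f.sum(), 1.0):
            raise ValueError("freqs must be 4 probabilities summing to 1")
        if self.kind == "markov1":
            if self.transition is None:
                raise ValueError("markov1 background needs a transition matrix")
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0):
                raise ValueError("transition rows must be 4x4 and sum to 1")
        elif self.kind != "iid":
            raise ValueError(f"unknown background kind {self.kind!r}")

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        f = np.asarray(self.freqs)
        if self.kind == "iid":
            return rng.choice(4, size=length, p=f)
        t = np.asarray(self.transition)
        out = np.empty(length, dtype=np.int8)
        out[0] = rng.choice(4, p=f)
        for i in range(1, length):
            out[i] = rng.choice(4, p=t[out[i - 1]])
        return out


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_sequences: int
    seq_length: int | tuple[int, int]
    spec: BipartiteSpec
    left_block: PwmBlock | ChainBlock
    right_block: PwmBlock | ChainBlock | None = None
    gap_weights: tuple | None = None  # over [gap_min, gap_max]; None = uniform
    background: Background = field(default_factory=Background)
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.left_block.width != self.spec.l_left:
            raise ValueError("left block width does not match spec")
        rb = self.right_block
        if self.spec.l_right and (rb is None or rb.width != self.spec.l_right):
            raise ValueError("right block width does not match spec")
        n_gaps = self.spec.gap_max - self.spec.gap_min + 1
        if self.gap_weights is not None:
            w = np.asarray(self.gap_weights, dtype=float)
            if w.shape != (n_gaps,) or w.sum() <= 0 or (w < 0).any():
                raise ValueError("gap_weights must be non-negative over the gap range")
        min_len = self.seq_length if isinstance(self.seq_length, int) else self.seq_length[0]
        if min_len < self.spec.span(self.spec.gap_max):
            raise ValueError(
                f"seq_length {min_len} too short for spec {self.spec} "
                f"(needs >= {self.spec.span(self.spec.gap_max)})"
            )


def _gap_probs(config: SynthConfig) -> np.ndarray:
    n_gaps = config.spec.gap_max - config.spec.gap_min + 1
    if config.gap_weights is None:
        return np.full(n_gaps, 1.0 / n_gaps)
    w = np.asarray(config.gap_weights, dtype=float)
    return w / w.sum()


def generate(
    config: SynthConfig,
) -> tuple[list[SequenceRecord], list[SiteAnnotation], dict[str, str]]:
    """Sample one dataset: (records, truth annotations, motif/noise labels).

    Fully reproducible from ``config.seed``.  Truth intervals cover block
    positions only (the planted gap is background text, matching the model
    semantics).
    """
    rng = np.random.default_rng(config.seed)
    spec = config.spec
    gap_probs = _gap_probs(config)
    n_noise = int(round(config.n_sequences * config.noise_fraction))
    noise_idx = set(
        rng.choice(config.n_sequences, size=n_noise, replace=False).tolist()
    )
    records: list[SequenceRecord] = []
    truth: list[SiteAnnotation] = []
    labels: dict[str, str] = {}
    for i in range(config.n_sequences):
        if isinstance(config.seq_length, int):
            L = config.seq_length
        else:
            L = int(rng.integers(config.seq_length[0], config.seq_length[1] + 1))
        sid = f"seq_{i + 1:04d}"
        bg = config.background.sample(L, rng)
        seq = list("".join(BASES[b] for b in bg))
        if i in noise_idx:
            labels[sid] = "noise"
        else:
            labels[sid] = "motif"
            gap = int(spec.gap_min + rng.choice(len(gap_probs), p=gap_probs))
            span = spec.span(gap)
            start = int(rng.integers(L - span + 1))
            left = config.left_block.sample(rng)
            seq[start : start + spec.l_left] = left
            ivals = [(start, start + spec.l_left)]
            if spec.l_right:
                right = config.right_block.sample(rng)
                rs = start + spec.l_left + gap
                seq[rs : rs + spec.l_right] = right
                ivals.append((rs, rs + spec.l_right))
            truth.append(SiteAnnotation(seq_id=sid, intervals=tuple(ivals)))
        records.append(SequenceRecord(id=sid, seq="".join(seq)))
    return records, truth, labels


def planted_placements(
    truth: Sequence[SiteAnnotation], records: Sequence[SequenceRecord], spec: BipartiteSpec
) -> list[Placement]:
    """Convert truth annotations back into Placement objects (for recovery
    comparisons against search output)."""
    index = {rec.id: i for i, rec in enumerate(records)}
    out = []
    for ann in truth:
        (a, b), *rest = ann.intervals
        gap = (rest[0][0] - b) if rest else 0
        out.append(Placement(seq_index=index[ann.seq_id], left_start=a, gap=gap))
    return out
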