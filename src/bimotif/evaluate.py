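"""Scoring predictions against known sites, and base-interdependency MI.

The headline statistic is the nucleotide-level correlation coefficient
(nCC), a Matthews-type correlation over per-base membership in known vs
predicted sites:

    nCC = (nTP*nTN - nFN*nFP) /
          sqrt((nTP+nFN)(nTN+nFP)(nTP+nFP)(nTN+nFN))

The "combined" nCC pools the four tallies over several datasets before
applying the formula once.  Sequence-level TPR/FPR summarise ZOOPS noise
detection: a "present" call on a motif-free (noise) sequence is a false
positive.  Pairwise mutual information between aligned site columns
quantifies base interdependency; it is the signal a dinucleotide model can
exploit and a mononucleotide model cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import encode
from .io_seq import DataError, SiteAnnotation
from .matrices import BipartiteSpec, Placement, block_intervals

__all__ = [
    "ConfusionCounts",
    "MIMatrix",
    "confusion",
    "ncc",
    "combined_ncc",
    "sequence_rates",
    "mutual_information",
    "placements_to_annotations",
    "write_mi_matrix",
]


@dataclass
class ConfusionCounts:
    """Per-nucleotide tallies: known/predicted membership of every position."""

    nTP: int = 0
    nFN: int = 0
    nFP: int = 0
    nTN: int = 0

    @property
    def total(self) -> int:
        return self.nTP + self.nFN + self.nFP + self.nTN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.nTP + other.nTP,
            self.nFN + other.nFN,
            self.nFP + other.nFP,
            self.nTN + other.nTN,
        )


def _mask(intervals, length: int, seq_id: str) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for start, end in intervals:
        if start < 0 or end > length:
            raise DataError(
                f"{seq_id}: interval [{start}, {end}) outside sequence of length {length}"
            )
        m[start:end] = True
    return m


def confusion(
    known: Sequence[SiteAnnotation],
    predicted: Sequence[SiteAnnotation],
    lengths: Mapping[str, int],
) -> ConfusionCounts:
    """Position-level confusion tallies over every sequence in ``lengths``.

    Sequences missing from either annotation set simply contribute no
    known/predicted positions; annotations for unknown ids are an error.
    """
    known_by = {a.seq_id: a for a in known}
    pred_by = {a.seq_id: a for a in predicted}
    for sid in list(known_by) + list(pred_by):
        if sid not in lengths:
            raise DataError(f"annotation references unknown sequence id {sid!r}")
    out = ConfusionCounts()
    for sid, length in lengths.items():
        km = _mask(known_by[sid].intervals if sid in known_by else (), length, sid)
        pm = _mask(pred_by[sid].intervals if sid in pred_by else (), length, sid)
        out.nTP += int((km & pm).sum())
        out.nFN += int((km & ~pm).sum())
        out.nFP += int((~km & pm).sum())
        out.nTN += int((~km & ~pm).sum())
    return out


def ncc(c: ConfusionCounts) -> float | None:
    """Nucleotide-level correlation coefficient, or None when any
    denominator factor is zero (never silently coerced to 0)."""
    denom = (
        (c.nTP + c.nFN) * (c.nTN + c.nFP) * (c.nTP + c.nFP) * (c.nTN + c.nFN)
    )
    if denom == 0:
        return None
    return (c.nTP * c.nTN - c.nFN * c.nFP) / math.sqrt(denom)


def combined_ncc(parts: Iterable[ConfusionCounts]) -> float | None:
    """Pool the four tallies across datasets, then apply the nCC formula once."""
    parts = list(parts)
    if not parts:
        raise ValueError("combined_ncc needs at least one part")
    total = ConfusionCounts()
    for p in parts:
        total = total + p
    return ncc(total)


def sequence_rates(
    truth_labels: Mapping[str, str], predictions: Mapping[str, bool]
) -> tuple[float | None, float | None]:
    """Sequence-level (TPR, FPR) for occurrence calls.

    ``truth_labels`` maps id -> "motif" | "noise"; ``predictions`` maps
    id -> called-present.  TPR = present calls among motif sequences;
    FPR = present calls among noise sequences.  Either rate is None when
    its class is empty.
    """
    missing = set(truth_labels) - set(predictions)
    if missing:
        raise DataError(f"predictions missing for ids: {sorted(missing)[:5]}")
    n_motif = n_noise = tp = fp = 0
    for sid, label in truth_labels.items():
        if label == "motif":
            n_motif += 1
            tp += bool(predictions[sid])
        elif label == "noise":
            n_noise += 1
            fp += bool(predictions[sid])
        else:
            raise DataError(f"{sid}: unknown label {label!r}")
    tpr = tp / n_motif if n_motif else None
    fpr = fp / n_noise if n_noise else None
    return tpr, fpr


@dataclass
class MIMatrix:
    """Symmetric position x position mutual information (bits) of aligned sites.

    The diagonal holds each column's marginal entropy (MI of a column with
    itself).
    """

    values: np.ndarray
    width: int


def mutual_information(sites: Sequence[str]) -> MIMatrix:
    """Pairwise MI over all column pairs of >= 2 equal-width A/C/G/T sites.

    Plain empirical frequencies, no pseudo-counts, with 0*log(0) := 0.
    """
    if len(sites) < 2:
        raise DataError("mutual_information needs at least 2 sites")
    width = len(sites[0])
    mat = np.zeros((len(sites), width), dtype=np.intp)
    for r, s in enumerate(sites):
        if len(s) != width:
            raise DataError(f"site {r} has width {len(s)} != {width}")
        enc = encode(s)
        if (enc > 3).any():
            raise DataError(f"site {r}: alphabet must be A/C/G/T")
        mat[r] = enc
    n = len(sites)
    values = np.zeros((width, width))
    marg = np.zeros((width, 4))
    for a in range(width):
        marg[a] = np.bincount(mat[:, a], minlength=4) / n
    for a in range(width):
        for b_ in range(a, width):
            joint = np.zeros((4, 4))
            np.add.at(joint, (mat[:, a], mat[:, b_]), 1.0)
            joint /= n
            indep = np.outer(marg[a], marg[b_])
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(joint > 0, joint * np.log2(joint / indep), 0.0)
            mi = float(terms.sum())
            values[a, b_] = values[b_, a] = mi
    return MIMatrix(values=values, width=width)


def write_mi_matrix(mi: MIMatrix, path) -> None:
    with open(path, "w") as fh:
        header = "\t".join(f"p{i + 1}" for i in range(mi.width))
        fh.write("pos\t" + header + "\n")
        for a in range(mi.width):
            row = "\t".join(f"{v:.6f}" for v in mi.values[a])
            fh.write(f"p{a + 1}\t{row}\n")


def placements_to_annotations(
    placements: Iterable[Placement],
    sequences: Sequence,
    spec: BipartiteSpec,
    count_gap_as_site: bool = False,
) -> list[SiteAnnotation]:
    """Predicted-site intervals of a placement set.

    By default only block positions count as predicted sites (the gap is
    unconstrained in the model); ``count_gap_as_site=True`` marks the whole
    left-to-right span instead, for sensitivity checks.
    """
    by_seq: dict[int, list[tuple[int, int]]] = {}
    for p in placements:
        if not p.present:
            continue
        seq = sequences[p.seq_index]
        length = len(seq.seq) if hasattr(seq, "seq") else len(seq)
        ivals = block_intervals(p, spec, length)
        if count_gap_as_site:
            ivals = [(min(a for a, _ in ivals), max(b for _, b in ivals))]
        by_seq.setdefault(p.seq_index, []).extend(ivals)
    out = []
    for i in sorted(by_seq):
        seq = sequences[i]
        sid = getattr(seq, "id", f"seq_{i + 1}")
        merged: list[tuple[int, int]] = []
        for a, b in sorted(by_seq[i]):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        out.append(SiteAnnotation(seq_id=sid, intervals=tuple(merged)))
    return out
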