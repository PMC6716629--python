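"""Reading sequence sets and site annotations; writing placement reports.

Two input dialects are accepted: standard (possibly multi-line) FASTA, and
plain text with one sequence per line where a line is either ``sequence`` or
``id<TAB>sequence`` (unlabelled lines get ids ``seq_1``, ``seq_2``, ...).
All coordinates in this package are 0-based half-open on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

from .alphabet import encode
from .matrices import BipartiteSpec, Placement

__all__ = [
    "SequenceRecord",
    "SiteAnnotation",
    "DataError",
    "read_sequences",
    "read_sites",
    "write_sites",
    "write_placements",
    "read_placements",
    "write_fasta",
]

VALID = set("ACGTN")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence over {A, C, G, T, N} (uppercased on load)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise DataError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SiteAnnotation:
    """Known or predicted site intervals for one sequence.

    ``intervals`` are 0-based half-open, sorted and non-overlapping.
    """

    seq_id: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if start < 0 or start >= end:
                raise DataError(
                    f"{self.seq_id}: invalid interval [{start}, {end})"
                )
            if start < prev_end:
                raise DataError(
                    f"{self.seq_id}: overlapping or unsorted intervals at [{start}, {end})"
                )
            prev_end = end


def _validate(rec_id: str, seq: str) -> str:
    seq = seq.upper()
    for off, ch in enumerate(seq):
        if ch not in VALID:
            raise DataError(
                f"record {rec_id!r}: illegal character {ch!r} at position {off}"
            )
    return seq


def read_sequences(path, format: str = "fasta") -> list[SequenceRecord]:
    """Load a sequence set from FASTA or one-sequence-per-line plain text.

    Sequences are uppercased; characters outside A/C/G/T/N, duplicate ids
    and empty files are rejected with a :class:`DataError`.
    """
    records: list[SequenceRecord] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(SequenceRecord(id=rec.id, seq=_validate(rec.id, str(rec.seq))))
    elif format == "plain":
        with open(path) as fh:
            idx = 0
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                idx += 1
                if "\t" in line:
                    rec_id, seq = line.split("\t", 1)
                else:
                    rec_id, seq = f"seq_{idx}", line
                records.append(SequenceRecord(id=rec_id, seq=_validate(rec_id, seq)))
    else:
        raise DataError(f"unknown sequence format {format!r}")
    if not records:
        raise DataError(f"no sequences in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def read_sites(path) -> list[SiteAnnotation]:
    """Read tab-delimited site annotations: ``seq_id  start  end`` per line.

    Intervals are grouped by id and sorted; an empty file is a valid empty
    annotation set.
    """
    by_id: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected seq_id<TAB>start<TAB>end")
            seq_id = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise DataError(f"{path}:{lineno}: start {start} >= end {end}")
            by_id.setdefault(seq_id, []).append((start, end))
            if seq_id not in order:
                order.append(seq_id)
    return [
        SiteAnnotation(seq_id=sid, intervals=tuple(sorted(by_id[sid])))
        for sid in order
    ]


def write_sites(annotations, path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for start, end in ann.intervals:
                fh.write(f"{ann.seq_id}\t{start}\t{end}\n")


_PLACEMENT_HEADER = (
    "seq_id\tleft_start\tleft_end\tgap_length\tright_start\tright_end"
    "\tstrand\tsite\tlog_odds"
)


def write_placements(result, path) -> None:
    """Write the tab-delimited placement report of a search result.

    One row per placement: coordinates (0-based half-open), the site string
    (left block + lowercase gap + right block) and the per-site log-odds
    score.  ZOOPS non-occurrences are emitted as a sentinel ``-`` row.
    """
    from .matrices import site_log_odds  # local to avoid cycle at import time

    spec: BipartiteSpec = result.spec
    seqs = {i: rec for i, rec in enumerate(result.sequences)}
    with open(path, "w") as fh:
        fh.write(f"# bimotif placements\tspec={spec}\tmode={spec.mode}\n")
        fh.write(_PLACEMENT_HEADER + "\n")
        for p in result.placements:
            rec = seqs[p.seq_index]
            if not p.present:
                fh.write(f"{rec.id}\t-\t-\t-\t-\t-\t-\t-\t-\n")
                continue
            seq = rec.seq
            if p.strand == "-":
                from .alphabet import decode, encode as _enc, reverse_complement

                seq = decode(reverse_complement(_enc(seq)))
            s = p.left_start
            le = s + spec.l_left
            rs = le + p.gap
            re_ = rs + spec.l_right
            site = seq[s:le] + seq[le:rs].lower() + seq[rs:re_]
            score = site_log_odds(
                result.model, rec.seq, p.left_start, p.gap, spec=spec, strand=p.strand
            )
            fh.write(
                f"{rec.id}\t{s}\t{le}\t{p.gap}\t{rs}\t{re_}\t{p.strand}\t{site}"
                f"\t{score:.17g}\n"
            )


def read_placements(path, id_to_index: dict[str, int]) -> list[Placement]:
    """Parse a placement report back into Placement objects (round trip)."""
    out: list[Placement] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("seq_id\t"):
                continue
            parts = line.split("\t")
            idx = id_to_index[parts[0]]
            if parts[1] == "-":
                out.append(Placement(seq_index=idx, left_start=-1, gap=0, present=False))
                continue
            out.append(
                Placement(
                    seq_index=idx,
                    left_start=int(parts[1]),
                    gap=int(parts[3]),
                    strand=parts[6],
                )
            )
    return out


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")
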