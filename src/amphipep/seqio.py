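"""Sequence I/O, maturation, candidate enumeration and similarity clustering.

Coordinates are 1-based and inclusive everywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


class ValidationError(ValueError):
    """Raised when input data violates a contract of this package."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional signal-peptide annotation.

    ``signal_end`` is the 1-based index of the last residue of the signal
    peptide; ``None`` means the sequence is already mature.
    """

    id: str
    sequence: str
    accessions: tuple[str, ...] = ()
    signal_end: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideCandidate:
    """A contiguous window of a parent protein (1-based, inclusive span)."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid span {self.start}-{self.end} on {self.parent_id!r}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}-{self.end} on {self.parent_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple[str, int, int]:
        return (self.parent_id, self.start, self.end)


@dataclass
class PeptideCluster:
    members: list[PeptideCandidate] = field(default_factory=list)
    representative: PeptideCandidate | None = None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the record id; any
    remaining '|'-separated tokens of that first word are kept as accessions.
    Sequences are uppercased. Duplicate ids raise :class:`ValidationError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValidationError(f"duplicate id in {path}: {rid!r}")
        seen.add(rid)
        accs = tuple(t for t in rid.split("|")[1:] if t)
        records.append(ProteinRecord(id=rid, sequence=str(rec.seq).upper(), accessions=accs))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def candidates_to_fasta(candidates: Iterable[PeptideCandidate], path: str | Path) -> None:
    """Export candidates with ``parent|start-end`` headers."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.parent_id}|{c.start}-{c.end}\n{c.sequence}\n")


def read_signal_table(path: str | Path) -> dict[str, int]:
    """Read a two-column delimited file mapping protein id -> signal_end."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 'id<TAB>signal_end'")
            table[parts[0]] = int(parts[1])
    return table


def mature_sequence(record: ProteinRecord) -> ProteinRecord:
    """Strip the annotated signal peptide, returning the mature record.

    A record without ``signal_end`` is returned unchanged.  Removing the whole
    sequence is forbidden.
    """
    if record.signal_end is None:
        return record
    if record.signal_end >= len(record.sequence):
        raise ValidationError(
            f"signal_end={record.signal_end} leaves no mature sequence for {record.id!r}"
        )
    if record.signal_end < 1:
        raise ValidationError(f"signal_end must be >= 1 for {record.id!r}")
    return replace(record, sequence=record.sequence[record.signal_end :], signal_end=None)


def enumerate_peptides(
    record: ProteinRecord, min_len: int = 7, max_len: int = 30
) -> list[PeptideCandidate]:
    """Enumerate every contiguous subsequence with min_len <= length <= max_len.

    Windows containing non-canonical residues (B, J, O, U, X, Z, ...) are
    skipped with a warning: hydrophobicity is undefined for them.
    """
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} > max_len {max_len}")
    seq = record.sequence
    bad = {i for i, aa in enumerate(seq) if aa not in CANONICAL}
    if bad:
        logger.warning(
            "protein %s: %d non-canonical residue(s); overlapping windows skipped",
            record.id,
            len(bad),
        )
    out: list[PeptideCandidate] = []
    n = len(seq)
    for length in range(min_len, min(max_len, n) + 1):
        for start0 in range(0, n - length + 1):
            if bad and any(start0 <= b < start0 + length for b in bad):
                continue
            out.append(
                PeptideCandidate(
                    parent_id=record.id,
                    start=start0 + 1,
                    end=start0 + length,
                    sequence=seq[start0 : start0 + length],
                )
            )
    return out


def similarity(a: str, b: str) -> float:
    """Ungapped sliding similarity: best fraction of identical positions when
    the shorter sequence is slid along the longer, denominator = shorter length.
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    w = len(short)
    best = 0
    for off in range(len(long_) - w + 1):
        ident = sum(1 for x, y in zip(short, long_[off : off + w]) if x == y)
        if ident > best:
            best = ident
            if best == w:
                break
    return best / w


def _linked_pairs(
    peptides: Sequence[PeptideCandidate], threshold: float
) -> "Iterable[tuple[int, int]]":
    """Yield index pairs whose sliding ungapped similarity exceeds threshold.

    Vectorized equivalent of calling :func:`similarity` on every pair: within
    each length pair the shorter sequences are compared against every window
    of the longer ones in one broadcast.
    """
    import numpy as np

    by_len: dict[int, list[int]] = {}
    for i, p in enumerate(peptides):
        by_len.setdefault(len(p.sequence), []).append(i)
    mats = {
        w: np.frombuffer(
            "".join(peptides[i].sequence for i in idx).encode("ascii"), dtype=np.uint8
        ).reshape(len(idx), w)
        for w, idx in by_len.items()
    }
    lengths = sorted(by_len)
    for wa in lengths:
        ia, a = by_len[wa], mats[wa]
        for wb in lengths:
            if wb < wa:
                continue
            ib, b = by_len[wb], mats[wb]
            windows = np.lib.stride_tricks.sliding_window_view(b, wa, axis=1)
            # chunk rows to cap the (chunk, nb, n_offsets, wa) broadcast size
            chunk = max(1, int(2e7 // max(1, windows.size)))
            for lo in range(0, len(a), chunk):
                sub = a[lo : lo + chunk]
                ident = (sub[:, None, None, :] == windows[None, :, :, :]).sum(axis=3).max(axis=2)
                for r, c in np.argwhere(ident > threshold * wa):
                    i, j = ia[lo + int(r)], ib[int(c)]
                    if i != j:
                        yield i, j


def cluster_peptides(
    peptides: Sequence[PeptideCandidate],
    similarity_threshold: float = 0.70,
    score_of: Callable[[PeptideCandidate], float] | None = None,
) -> list[PeptideCluster]:
    """Single-linkage clustering of peptides under similarity > threshold.

    The representative is the highest-scoring member (``score_of``; defaults
    to 0 for all), ties broken by greater length then lexicographic sequence.
    Output is deterministic and invariant to input order.
    """
    n = len(peptides)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i, j in _linked_pairs(peptides, similarity_threshold):
        union(i, j)

    groups: dict[int, list[PeptideCandidate]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peptides[i])

    score = score_of or (lambda p: 0.0)
    clusters = []
    for members in groups.values():
        members = sorted(members, key=lambda p: (p.sequence, p.key()))
        rep = max(members, key=lambda p: (score(p), p.length, p.sequence))
        clusters.append(PeptideCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.representative.sequence)
    return clusters
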