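"""Ungapped best-hit read-to-ORF assignment and per-ORF read counting.

The mapping contract: each read is placed at the offset (over every ORF,
every offset, both strands) with the fewest mismatches, kept only if
that minimum is at most ``max_mismatches`` (default 2, over the entire
read, no gaps).  ``N`` never matches anything.  Ties are broken
deterministically by (orf_id lexicographic, smallest offset, then +
strand), so a read contributes to at most one ORF.

The implementation uses a pigeonhole seed index: a read with at most m
mismatches must contain at least one of m+1 disjoint exact segments, so
looking up those segments in a k-mer position table and verifying each
candidate offset finds exactly the same winners as the full scan —
provably, whenever the best alignment has <= max_mismatches — while
staying fast enough to map whole synthetic communities.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .errors import InputError
from .io_formats import OrfRecord, ReadAlignment
from .simulate import revcomp


class OrfIndex:
    """Seed index over a set of ORF nucleotide sequences."""

    def __init__(self, orf_seqs: Mapping[str, str], max_mismatches: int = 2):
        if max_mismatches < 0:
            raise InputError("max_mismatches must be >= 0")
        self.orf_seqs = dict(orf_seqs)
        self.max_mismatches = max_mismatches
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        """k-mer -> [(orf_id, position)] over all forward ORF sequences."""
        if k not in self._tables:
            table: dict[str, list[tuple[str, int]]] = {}
            for orf_id in sorted(self.orf_seqs):
                seq = self.orf_seqs[orf_id]
                for pos in range(len(seq) - k + 1):
                    table.setdefault(seq[pos:pos + k], []).append((orf_id, pos))
            self._tables[k] = table
        return self._tables[k]

    def _candidates(self, read: str) -> set[tuple[str, int]]:
        """All (orf_id, offset) that could hold the read within the mismatch budget."""
        k = max(1, len(read) // (self.max_mismatches + 1))
        table = self._table(k)
        cands: set[tuple[str, int]] = set()
        for j in range(self.max_mismatches + 1):
            seg = read[j * k:(j + 1) * k]
            if len(seg) < k:
                break
            for orf_id, pos in table.get(seg, ()):
                off = pos - j * k
                if off >= 0 and off + len(read) <= len(self.orf_seqs[orf_id]):
                    cands.add((orf_id, off))
        return cands

    def best_alignment(self, read_id: str, read: str) -> ReadAlignment | None:
        """Best ungapped placement of the read, or None if none is good enough."""
        if not read:
            raise InputError(f"read {read_id!r} is empty")
        read = read.upper()
        best: tuple[int, str, int, int] | None = None  # (mm, orf_id, offset, strand_order)
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            for orf_id, off in self._candidates(oriented):
                seq = self.orf_seqs[orf_id]
                mm = _count_mismatches(oriented, seq, off, self.max_mismatches)
                if mm > self.max_mismatches:
                    continue
                key = (mm, orf_id, off, 0 if strand == "+" else 1)
                if best is None or key < best:
                    best = key
        if best is None:
            return None
        mm, orf_id, off, s = best
        return ReadAlignment(read_id=read_id, orf_id=orf_id, offset=off,
                             strand="+" if s == 0 else "-", mismatches=mm)


def _count_mismatches(read: str, seq: str, offset: int, limit: int) -> int:
    """Mismatches of read vs seq[offset:], early-exiting past the limit; N never matches."""
    mm = 0
    for a, b in zip(read, seq[offset:offset + len(read)]):
        if a != b or a == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def best_ungapped_alignment(
    read: str,
    orf_seqs: Mapping[str, str] | OrfIndex,
    max_mismatches: int = 2,
    read_id: str = "read",
) -> ReadAlignment | None:
    """One-shot best placement of a single read (see :class:`OrfIndex`)."""
    index = orf_seqs if isinstance(orf_seqs, OrfIndex) else OrfIndex(orf_seqs, max_mismatches)
    return index.best_alignment(read_id, read)


def align_reads(
    reads: Sequence[tuple[str, str]],
    orf_seqs: Mapping[str, str],
    max_mismatches: int = 2,
) -> list[ReadAlignment]:
    """Map many (read_id, sequence) pairs; unalignable reads are dropped."""
    index = OrfIndex(orf_seqs, max_mismatches)
    out: list[ReadAlignment] = []
    for read_id, seq in reads:
        aln = index.best_alignment(read_id, seq)
        if aln is not None:
            out.append(aln)
    return out


def count_reads_per_orf(
    alignments: Sequence[ReadAlignment],
    orfs: Mapping[str, OrfRecord] | Sequence[OrfRecord],
) -> dict[str, int]:
    """Reads per ORF; every ORF appears (zero allowed) and counts sum to len(alignments)."""
    if not isinstance(orfs, Mapping):
        orfs = {o.orf_id: o for o in orfs}
    counts = {orf_id: 0 for orf_id in orfs}
    for aln in alignments:
        if aln.orf_id not in counts:
            raise InputError(f"alignment of {aln.read_id} references unknown ORF {aln.orf_id!r}")
        counts[aln.orf_id] += 1
    return counts
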