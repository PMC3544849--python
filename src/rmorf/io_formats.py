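"""Readers and writers for the standard formats the pipeline touches.

Everything downstream consumes only the in-memory records defined here:
:class:`OrfRecord`, :class:`ReadAlignment`, :class:`ProteinHit` and
:class:`DomainHit`.  Internal coordinates are 0-based half-open; GFF3 is
read and written as 1-based inclusive with the conversion confined to
this module.  All tabular files are TSV with ``#``-prefixed header lines
and are read gzip-transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

log = logging.getLogger(__name__)

#: default homology-hit E-value ceiling applied at read time
PROTEIN_EVALUE_CUTOFF = 1e-5
#: default domain-hit E-value ceiling (screening happens later in cazy_screen;
#: the reader itself keeps every parseable row below this very loose bound)
DOMAIN_EVALUE_CUTOFF = float("inf")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfRecord:
    """A predicted protein-coding gene on a contig.

    ``start``/``end`` are 0-based half-open nucleotide positions on the
    contig.  ``length_aa`` excludes the stop codon when the ORF is
    full-length (both start and stop codon present).
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    full_length: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(f"ORF {self.orf_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise InputError(f"ORF {self.orf_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        codons = self.length_nt // 3
        return codons - 1 if self.full_length else codons


@dataclass(frozen=True)
class ReadAlignment:
    """One read placed ungapped on one ORF."""

    read_id: str
    orf_id: str
    offset: int          # 0-based read start on the ORF
    strand: str
    mismatches: int


@dataclass(frozen=True)
class ProteinHit:
    """A protein homology hit (BLAST-style) carrying a subject taxon."""

    orf_id: str
    subject_id: str
    bit_score: float
    evalue: float
    identity_pct: float
    subject_taxon: str


@dataclass(frozen=True)
class DomainHit:
    """A protein-domain hit (Pfam-scan style), 1-based inclusive residues."""

    orf_id: str
    domain_acc: str
    evalue: float
    score: float
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if self.ali_from > self.ali_to:
            raise InputError(
                f"domain hit on {self.orf_id}: ali_from ({self.ali_from}) > ali_to ({self.ali_to})"
            )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Duplicate ids and empty sequences are hard errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise InputError(f"{path}: duplicate sequence id {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise InputError(f"{path}: empty sequence for id {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, seq))
    log.info("read %d FASTA records from %s", len(records), path)
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write records as FASTA wrapped at 60 columns (round-trips with read_fasta)."""
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read 4-line FASTQ into ``[(id, sequence, quality_string), ...]``."""
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3 (ORF coordinates)
# ---------------------------------------------------------------------------

def write_gff3_orfs(path: str | Path, orfs: Sequence[OrfRecord]) -> None:
    """Write ORFs as GFF3 CDS features (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            attrs = f"ID={o.orf_id};full_length={'true' if o.full_length else 'false'}"
            fh.write(
                f"{o.contig_id}\trmorf\tCDS\t{o.start + 1}\t{o.end}\t.\t{o.strand}\t0\t{attrs}\n"
            )


def read_gff3_orfs(path: str | Path) -> list[OrfRecord]:
    """Read CDS features back into :class:`OrfRecord` (converting to 0-based half-open)."""
    orfs: list[OrfRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            contig, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            orf_id = attr_map.get("ID")
            if orf_id is None:
                raise InputError(f"{path}:{lineno}: CDS feature without ID attribute")
            if orf_id in seen:
                raise InputError(f"{path}:{lineno}: duplicate ORF id {orf_id!r}")
            seen.add(orf_id)
            orfs.append(
                OrfRecord(
                    orf_id=orf_id,
                    contig_id=contig,
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    full_length=attr_map.get("full_length", "true") == "true",
                )
            )
    return orfs


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam_alignments(
    path: str | Path,
    orfs: dict[str, OrfRecord] | Sequence[OrfRecord],
    max_mismatches: int = 2,
) -> list[ReadAlignment]:
    """Read a SAM file of reads-vs-ORFs alignments.

    Unmapped records (flag 0x4) are skipped; records whose NM tag exceeds
    ``max_mismatches`` are skipped; a missing NM tag is treated as 0
    mismatches with a warning.  An RNAME naming an unknown ORF is a hard
    error.
    """
    if not isinstance(orfs, dict):
        orfs = {o.orf_id: o for o in orfs}
    out: list[ReadAlignment] = []
    n_unmapped = n_overmm = 0
    warned_nm = False
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, rec in enumerate(sam.fetch(until_eof=True), 1):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            rname = rec.reference_name
            if rname not in orfs:
                raise InputError(
                    f"{path}: record {i} ({rec.query_name}): RNAME {rname!r} is not a known ORF"
                )
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                nm = 0
                if not warned_nm:
                    log.warning("%s: records without NM tag treated as 0 mismatches", path)
                    warned_nm = True
            if nm > max_mismatches:
                n_overmm += 1
                log.debug("%s: record %d rejected, NM=%d > %d", path, i, nm, max_mismatches)
                continue
            read_len = rec.query_length or rec.infer_query_length() or 0
            offset = rec.reference_start
            if offset + read_len > orfs[rname].length_nt:
                raise InputError(
                    f"{path}: record {i}: alignment extends past end of ORF {rname}"
                )
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    orf_id=rname,
                    offset=offset,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=nm,
                )
            )
    log.info(
        "%s: kept %d alignments (%d unmapped skipped, %d over mismatch limit)",
        path, len(out), n_unmapped, n_overmm,
    )
    return out


# ---------------------------------------------------------------------------
# tabular hits (BLAST outfmt-6-like, Pfam-scan-like)
# ---------------------------------------------------------------------------

def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_tabular_hits(
    path: str | Path,
    kind: str,
    evalue_cutoff: float | None = None,
) -> list[ProteinHit] | list[DomainHit]:
    """Read a tab-separated hit table.

    ``kind='protein'`` expects 13 columns following the BLAST
    ``outfmt '6 std staxids'`` convention (the 12 standard columns plus a
    subject-taxon column); rows with E-value above the cutoff (default
    1e-5) are rejected at read time.  ``kind='domain'`` expects 6 columns:
    orf_id, domain_acc, evalue, score, ali_from, ali_to.
    """
    if kind not in ("protein", "domain"):
        raise ValueError(f"kind must be 'protein' or 'domain', got {kind!r}")
    out: list = []
    n_rejected = 0
    if kind == "protein":
        cutoff = PROTEIN_EVALUE_CUTOFF if evalue_cutoff is None else evalue_cutoff
        for lineno, cols in _rows(path):
            if len(cols) != 13:
                raise InputError(f"{path}:{lineno}: expected 13 columns, got {len(cols)}")
            try:
                hit = ProteinHit(
                    orf_id=cols[0],
                    subject_id=cols[1],
                    identity_pct=float(cols[2]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                    subject_taxon=cols[12],
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if hit.evalue > cutoff:
                n_rejected += 1
                log.debug("%s:%d rejected: evalue %.3g > %.3g", path, lineno, hit.evalue, cutoff)
                continue
            out.append(hit)
    else:
        cutoff = DOMAIN_EVALUE_CUTOFF if evalue_cutoff is None else evalue_cutoff
        for lineno, cols in _rows(path):
            if len(cols) != 6:
                raise InputError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            try:
                hit = DomainHit(
                    orf_id=cols[0],
                    domain_acc=cols[1],
                    evalue=float(cols[2]),
                    score=float(cols[3]),
                    ali_from=int(cols[4]),
                    ali_to=int(cols[5]),
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if hit.evalue > cutoff:
                n_rejected += 1
                continue
            out.append(hit)
    log.info("%s: kept %d %s hits (%d rejected by E-value)", path, len(out), kind, n_rejected)
    return out


def write_protein_hits(path: str | Path, hits: Iterable[ProteinHit]) -> None:
    """Write hits in the 13-column layout read_tabular_hits expects."""
    with open(path, "w") as fh:
        fh.write("# qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\tqstart\tqend\tsstart\tsend\tevalue\tbitscore\tstaxids\n")
        for h in hits:
            fh.write(
                f"{h.orf_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.3g}\t{h.bit_score:.1f}\t{h.subject_taxon}\n"
            )


def write_domain_hits(path: str | Path, hits: Iterable[DomainHit]) -> None:
    with open(path, "w") as fh:
        fh.write("# orf_id\tdomain_acc\tevalue\tscore\tali_from\tali_to\n")
        for h in hits:
            fh.write(f"{h.orf_id}\t{h.domain_acc}\t{h.evalue:.3g}\t{h.score:.1f}\t{h.ali_from}\t{h.ali_to}\n")


# ---------------------------------------------------------------------------
# taxonomy table
# ---------------------------------------------------------------------------

def read_taxonomy_table(path: str | Path):
    """Read a taxonomy TSV (taxon_id, parent_id, rank, name) into a TaxonomyTree.

    The root is the unique row whose parent is empty or names itself.
    Cycles, orphan parents and multiple roots are hard errors.
    """
    from .taxonomy import TaxonomyTree

    nodes: dict[str, tuple[str, str, str]] = {}
    for lineno, cols in _rows(path):
        if len(cols) != 4:
            raise InputError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
        taxon_id, parent_id, rank, name = cols
        if taxon_id in nodes:
            raise InputError(f"{path}:{lineno}: duplicate taxon id {taxon_id!r}")
        nodes[taxon_id] = (parent_id, rank, name)
    return TaxonomyTree.from_rows(
        [(t, p, r, n) for t, (p, r, n) in nodes.items()]
    )


def write_taxonomy_table(path: str | Path, tree) -> None:
    with open(path, "w") as fh:
        fh.write("# taxon_id\tparent_id\trank\tname\n")
        for taxon_id in tree.nodes:
            parent, rank, name = tree.nodes[taxon_id]
            parent_out = "" if taxon_id == tree.root else parent
            fh.write(f"{taxon_id}\t{parent_out}\t{rank}\t{name}\n")


# ---------------------------------------------------------------------------
# simple TSV tables used between stages
# ---------------------------------------------------------------------------

def write_counts_table(path: str | Path, counts: dict[str, int], orfs: dict[str, OrfRecord]) -> None:
    """Write per-ORF read counts: orf_id, length_nt, n_reads."""
    with open(path, "w") as fh:
        fh.write("# orf_id\tlength_nt\tn_reads\n")
        for orf_id in sorted(counts):
            fh.write(f"{orf_id}\t{orfs[orf_id].length_nt}\t{counts[orf_id]}\n")


def read_counts_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read counts TSV into ``{orf_id: (length_nt, n_reads)}``."""
    out: dict[str, tuple[int, int]] = {}
    for lineno, cols in _rows(path):
        if len(cols) != 3:
            raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        out[cols[0]] = (int(cols[1]), int(cols[2]))
    return out


def write_orf_taxa(path: str | Path, assignments: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("# orf_id\ttaxon_id\n")
        for orf_id in sorted(assignments):
            fh.write(f"{orf_id}\t{assignments[orf_id]}\n")


def read_orf_taxa(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, cols in _rows(path):
        if len(cols) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        out[cols[0]] = cols[1]
    return out
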