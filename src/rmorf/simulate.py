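"""Synthetic metagenome community generator.

Produces a fully labelled community — genome sequences, a taxonomy,
non-overlapping ORFs, 100 bp paired-end reads with substitution errors,
protein homology hits and protein-domain hits — with the statistical
structure the downstream analysis assumes: abundance tiers that produce
distinct read-coverage trends, a dominant cellulolytic phylum, and a
tunable fraction of taxonomically dark ORFs.  Truth tables accompany
every simulated artifact so each downstream stage can be scored against
known labels.

All randomness flows through numpy generators derived from the spec
seed, so identical spec + seed reproduces identical output byte for
byte.  The error model is substitution-only: the read-mapping contract
downstream is ungapped, so simulated indels would only create
unmappable reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .io_formats import DomainHit, OrfRecord, ProteinHit
from .taxonomy import RANK_ORDER, TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# community specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """One member genome: id, lineage root->genus, size, abundance, gene density."""

    genome_id: str
    lineage: tuple[str, ...]          # taxon names, root first, at most len(RANK_ORDER)
    genome_length: int                # nt
    target_coverage: float            # fold
    gene_density: float = 0.5         # ORFs per kb


@dataclass(frozen=True)
class CommunitySpec:
    """Generative description of the synthetic metagenome."""

    genomes: tuple[GenomeSpec, ...]
    read_length: int = 100
    error_rate: float = 0.0
    insert_size_mean: float = 180.0
    insert_size_sd: float = 20.0
    p_nohit: float = 0.0              # probability an ORF gets no homology hits
    p_offtarget: float = 0.0          # probability a non-top hit points to a wrong taxon
    seed: int = 0
    orf_length_range: tuple[int, int] = (300, 3000)
    score_gap: float = 0.15           # off-target bit scores sit below (1-gap) x top
    identity_beta: tuple[float, float] = (1.0, 1.4)
    identity_range: tuple[float, float] = (20.0, 100.0)

    def __post_init__(self) -> None:
        if not self.genomes:
            raise InputError("community needs at least one genome")
        for g in self.genomes:
            if g.target_coverage <= 0:
                raise InputError(f"{g.genome_id}: target_coverage must be > 0")
            if len(g.lineage) < 1 or len(g.lineage) > len(RANK_ORDER):
                raise InputError(f"{g.genome_id}: lineage length must be 1..{len(RANK_ORDER)}")
        roots = {g.lineage[0] for g in self.genomes}
        if len(roots) != 1:
            raise InputError(f"all lineages must share a single root, found {roots}")
        if not (0 <= self.error_rate < 0.25):
            raise InputError(f"error_rate must be in [0, 0.25), got {self.error_rate}")
        for name, p in (("p_nohit", self.p_nohit), ("p_offtarget", self.p_offtarget)):
            if not (0 <= p <= 1):
                raise InputError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ReadTruth:
    """Where a simulated read really came from (0-based half-open on genome)."""

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str


@dataclass
class Community:
    """The labelled output of :func:`build_community`."""

    spec: CommunitySpec
    genomes: dict[str, str]                    # genome_id -> sequence
    orfs: list[OrfRecord]
    orf_seqs: dict[str, str]                   # orf_id -> nt sequence (strand-resolved)
    tree: TaxonomyTree
    truth: dict[str, str]                      # orf_id -> true (deepest) taxon id

    @property
    def orf_index(self) -> dict[str, OrfRecord]:
        return {o.orf_id: o for o in self.orfs}


def _rng(spec: CommunitySpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stage]))


def taxonomy_from_lineages(genomes: Sequence[GenomeSpec]) -> TaxonomyTree:
    """Build a rank-labelled tree by merging lineages on shared prefixes.

    Taxon names serve as taxon ids; ranks are assigned positionally from
    the canonical rank order (root, superkingdom, phylum, ...).
    """
    rows: dict[str, tuple[str, str, str]] = {}
    for g in genomes:
        for i, name in enumerate(g.lineage):
            parent = g.lineage[i - 1] if i > 0 else name
            rank = RANK_ORDER[i]
            if name in rows and rows[name] != (parent, rank, name):
                raise InputError(f"taxon {name!r} appears with conflicting parent or rank")
            rows[name] = (parent, rank, name)
    return TaxonomyTree.from_rows([(t, p, r, n) for t, (p, r, n) in rows.items()])


# ---------------------------------------------------------------------------
# genomes and ORFs
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _place_orfs(
    rng: np.random.Generator, gspec: GenomeSpec, lo: int, hi: int, max_tries: int = 100
) -> list[tuple[int, int]]:
    """Non-overlapping (start, end) intervals; lengths uniform multiples of 3."""
    n_orfs = int(round(gspec.gene_density * gspec.genome_length / 1000.0))
    if n_orfs == 0:
        return []
    if n_orfs * lo > gspec.genome_length:
        raise InputError(
            f"{gspec.genome_id}: gene density {gspec.gene_density}/kb infeasible for "
            f"{gspec.genome_length} nt genome (needs >= {n_orfs * lo} nt of ORFs)"
        )
    for _ in range(max_tries):
        lengths = (rng.integers(lo // 3, hi // 3 + 1, size=n_orfs) * 3).astype(int)
        slack = gspec.genome_length - int(lengths.sum())
        if slack >= 0:
            break
    else:
        raise InputError(
            f"{gspec.genome_id}: could not place {n_orfs} ORFs of {lo}-{hi} nt "
            f"on a {gspec.genome_length} nt genome"
        )
    # distribute the slack into n_orfs + 1 gaps via sorted uniform cuts
    cuts = np.sort(rng.integers(0, slack + 1, size=n_orfs))
    gaps = np.diff(np.concatenate([[0], cuts]))
    intervals = []
    pos = 0
    for length, gap in zip(lengths, gaps):
        pos += int(gap)
        intervals.append((pos, pos + int(length)))
        pos += int(length)
    return intervals


def build_community(spec: CommunitySpec) -> Community:
    """Generate genomes, taxonomy, ORFs and the ORF->taxon truth table."""
    tree = taxonomy_from_lineages(spec.genomes)
    rng = _rng(spec, 0)
    lo, hi = spec.orf_length_range
    genomes: dict[str, str] = {}
    orfs: list[OrfRecord] = []
    orf_seqs: dict[str, str] = {}
    truth: dict[str, str] = {}
    for gspec in spec.genomes:
        seq = _random_seq(rng, gspec.genome_length)
        genomes[gspec.genome_id] = seq
        intervals = _place_orfs(rng, gspec, lo, hi)
        for k, (start, end) in enumerate(intervals):
            strand = "+" if rng.random() < 0.5 else "-"
            orf_id = f"{gspec.genome_id}_orf{k:04d}"
            rec = OrfRecord(orf_id=orf_id, contig_id=gspec.genome_id,
                            start=start, end=end, strand=strand)
            orfs.append(rec)
            sub = seq[start:end]
            orf_seqs[orf_id] = sub if strand == "+" else revcomp(sub)
            truth[orf_id] = gspec.lineage[-1]
    return Community(spec=spec, genomes=genomes, orfs=orfs, orf_seqs=orf_seqs,
                     tree=tree, truth=truth)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_reads(
    community: Community, spec: CommunitySpec | None = None
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], list[ReadTruth]]:
    """Simulate paired-end reads from the community genomes.

    Per genome the read count is round(coverage x length / read_length),
    split into pairs; fragments are drawn from both strands, and
    substitution errors applied iid at ``error_rate``.  Returns
    ``(r1_records, r2_records, truth)`` where each record is
    (read_id, sequence, quality) and mate ids share a stem with /1, /2
    suffixes.
    """
    spec = spec or community.spec
    rng = _rng(spec, 1)
    rl = spec.read_length
    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    truth: list[ReadTruth] = []
    qual = "I" * rl
    for gspec in spec.genomes:
        seq = community.genomes[gspec.genome_id]
        glen = len(seq)
        if glen < rl:
            raise InputError(f"{gspec.genome_id}: genome shorter than read length")
        n_reads = int(round(gspec.target_coverage * glen / rl))
        n_pairs = int(round(n_reads / 2))
        inserts = np.clip(
            np.rint(rng.normal(spec.insert_size_mean, spec.insert_size_sd, size=n_pairs)),
            rl, glen,
        ).astype(int)
        starts = rng.integers(0, glen - inserts + 1)
        fwd = rng.random(n_pairs) < 0.5
        for k in range(n_pairs):
            ins, start = int(inserts[k]), int(starts[k])
            end = start + ins
            stem = f"{gspec.genome_id}_r{k:07d}"
            left = seq[start:start + rl]
            right = revcomp(seq[end - rl:end])
            if fwd[k]:
                a, b = left, right
                t1 = ReadTruth(f"{stem}/1", gspec.genome_id, start, start + rl, "+")
                t2 = ReadTruth(f"{stem}/2", gspec.genome_id, end - rl, end, "-")
            else:
                a, b = right, left
                t1 = ReadTruth(f"{stem}/1", gspec.genome_id, end - rl, end, "-")
                t2 = ReadTruth(f"{stem}/2", gspec.genome_id, start, start + rl, "+")
            r1.append((f"{stem}/1", _mutate(rng, a, spec.error_rate), qual))
            r2.append((f"{stem}/2", _mutate(rng, b, spec.error_rate), qual))
            truth.extend([t1, t2])
    return r1, r2, truth


def simulate_orf_reads(
    orf_seqs: Mapping[str, str],
    n_reads: int,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Draw single reads from ORF interiors (both strands).

    Returns ``([(read_id, sequence)], read_id -> source orf_id)``.
    Sampling is uniform over all eligible (orf, offset) start positions,
    so longer ORFs receive proportionally more reads.
    """
    rng = np.random.default_rng(seed)
    eligible = [(oid, s) for oid, s in sorted(orf_seqs.items()) if len(s) >= read_length]
    if not eligible:
        raise InputError("no ORF is long enough for the requested read length")
    weights = np.array([len(s) - read_length + 1 for _, s in eligible], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(eligible), size=n_reads, p=weights)
    reads: list[tuple[str, str]] = []
    source: dict[str, str] = {}
    for i, pick in enumerate(picks):
        oid, seq = eligible[int(pick)]
        off = int(rng.integers(0, len(seq) - read_length + 1))
        sub = seq[off:off + read_length]
        if rng.random() < 0.5:
            sub = revcomp(sub)
        sub = _mutate(rng, sub, error_rate)
        rid = f"simread{i:06d}"
        reads.append((rid, sub))
        source[rid] = oid
    return reads, source


def true_orf_counts(truth: Sequence[ReadTruth], orfs: Sequence[OrfRecord]) -> dict[str, int]:
    """Count reads whose true span lies fully inside an ORF (label-based oracle)."""
    by_genome: dict[str, list[OrfRecord]] = {}
    for o in orfs:
        by_genome.setdefault(o.contig_id, []).append(o)
    for lst in by_genome.values():
        lst.sort(key=lambda o: o.start)
    counts = {o.orf_id: 0 for o in orfs}
    for t in truth:
        for o in by_genome.get(t.genome_id, ()):
            if o.start <= t.start and t.end <= o.end:
                counts[o.orf_id] += 1
                break
            if o.start > t.start:
                break
    return counts


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

def simulate_protein_hits(
    community: Community, spec: CommunitySpec | None = None
) -> list[ProteinHit]:
    """Simulate a BLAST-vs-reference hit table with known structure.

    With probability 1-p_nohit an ORF receives 3-10 hits; the true
    taxon's hit carries the top bit score, while off-target hits
    (probability p_offtarget each) point to a random other genus with
    scores at least ``score_gap`` below the top, so that default
    top-percent filtering separates true from off-target evidence.
    Identity percentages follow a scaled Beta so identity histograms are
    exercisable.
    """
    spec = spec or community.spec
    rng = _rng(spec, 2)
    tree = community.tree
    genera = sorted(
        t for t in tree.nodes if t != tree.root and not any(
            tree.parent(o) == t for o in tree.nodes if o != t
        )
    )
    a, b = spec.identity_beta
    ilo, ihi = spec.identity_range
    hits: list[ProteinHit] = []
    for orf in community.orfs:
        if rng.random() < spec.p_nohit:
            continue
        true_taxon = community.truth[orf.orf_id]
        n_hits = int(rng.integers(3, 11))
        top = float(rng.uniform(100.0, 400.0))
        for k in range(n_hits):
            if k == 0:
                taxon, score = true_taxon, top
            elif rng.random() < spec.p_offtarget and len(genera) > 1:
                others = [g for g in genera if g != true_taxon]
                taxon = others[int(rng.integers(0, len(others)))]
                score = float(rng.uniform(0.5, 1.0 - spec.score_gap) * top)
            else:
                taxon = true_taxon
                score = float(rng.uniform(1.0 - spec.score_gap / 2.0, 1.0) * top)
            hits.append(
                ProteinHit(
                    orf_id=orf.orf_id,
                    subject_id=f"ref|{taxon}|{k}",
                    bit_score=round(score, 1),
                    evalue=float(10.0 ** -rng.uniform(6.0, 50.0)),
                    identity_pct=round(float(ilo + (ihi - ilo) * rng.beta(a, b)), 1),
                    subject_taxon=taxon,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# domain hits
# ---------------------------------------------------------------------------

def simulate_domain_hits(
    orfs: Sequence[OrfRecord],
    cazy_map,
    p_cazy: float = 0.3,
    family_weights: Mapping[str, float] | None = None,
    decoy_fraction: float = 0.1,
    evalue_cutoff: float = 1e-4,
    seed: int = 0,
) -> tuple[list[DomainHit], dict[str, list[str]]]:
    """Simulate a Pfam-scan-style domain hit table.

    ``cazy_map`` is a sequence of CazyMapEntry.  Each ORF is
    carbohydrate-active with probability ``p_cazy`` and then gets 1-3
    sub-cutoff hits with families drawn from ``family_weights``; a
    ``decoy_fraction`` of ORFs additionally receives hits that the
    screen must reject (non-CAZy accessions or over-cutoff E-values).
    Returns ``(hits, truth)`` where truth maps each genuinely
    carbohydrate-active ORF to its list of true families.
    """
    rng = np.random.default_rng(seed)
    fam_to_accs: dict[str, list[str]] = {}
    for e in cazy_map:
        fam_to_accs.setdefault(e.cazy_family, []).append(e.domain_acc)
    families = sorted(fam_to_accs)
    if family_weights is None:
        weights = np.ones(len(families))
    else:
        unknown = set(family_weights) - set(families)
        if unknown:
            raise InputError(f"family weights name families absent from the map: {sorted(unknown)}")
        weights = np.array([family_weights.get(f, 0.0) for f in families], dtype=float)
    if families and weights.sum() > 0:
        weights = weights / weights.sum()
    hits: list[DomainHit] = []
    truth: dict[str, list[str]] = {}
    for orf in orfs:
        if families and weights.sum() > 0 and rng.random() < p_cazy:
            n = int(rng.integers(1, 4))
            fams = [families[int(i)] for i in rng.choice(len(families), size=n, p=weights)]
            truth[orf.orf_id] = fams
            for fam in fams:
                accs = fam_to_accs[fam]
                acc = accs[int(rng.integers(0, len(accs)))]
                lo = max(1, orf.length_aa // 4)
                hi = max(lo + 1, orf.length_aa)
                ali_from = int(rng.integers(1, max(2, orf.length_aa - lo + 1)))
                ali_to = min(orf.length_aa, ali_from + int(rng.integers(lo, hi)) - 1)
                hits.append(
                    DomainHit(
                        orf_id=orf.orf_id, domain_acc=acc,
                        evalue=float(10.0 ** -rng.uniform(5.0, 30.0)),
                        score=round(float(rng.uniform(20.0, 200.0)), 1),
                        ali_from=ali_from, ali_to=ali_to,
                    )
                )
        if rng.random() < decoy_fraction:
            if families and rng.random() < 0.5:
                # genuine CAZy accession but an E-value above the screen cutoff
                fam = families[int(rng.integers(0, len(families)))]
                acc = fam_to_accs[fam][0]
                ev = float(evalue_cutoff * 10.0 ** rng.uniform(0.5, 3.0))
            else:
                acc = f"PF9{int(rng.integers(0, 1000)):04d}"
                ev = float(10.0 ** -rng.uniform(5.0, 30.0))
            hits.append(
                DomainHit(
                    orf_id=orf.orf_id, domain_acc=acc, evalue=ev,
                    score=round(float(rng.uniform(5.0, 40.0)), 1),
                    ali_from=1, ali_to=max(1, min(orf.length_aa, 50)),
                )
            )
    return hits, truth


# ---------------------------------------------------------------------------
# the packaged three-tier preset
# ---------------------------------------------------------------------------

def fig1_preset(
    seed: int = 0,
    genome_length: int = 50_000,
    gene_density: float = 0.5,
    error_rate: float = 0.002,
    p_nohit: float = 0.128,
    p_offtarget: float = 0.05,
) -> CommunitySpec:
    """Three-tier community mirroring the published coverage structure.

    One genome per abundance tier at 112x / 29x / 8x fold coverage,
    labelled Firmicutes / Chloroflexi / Euryarchaeota: a dominant
    cellulolytic Clostridium, a mid-tier Anaerolinea and a low-tier
    methanogen.  ``p_nohit`` defaults to the fraction of taxonomically
    dark ORFs reported for the real sludge (12.8%).
    """
    genomes = (
        GenomeSpec(
            "g_clostridium",
            ("root", "Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
             "Clostridiaceae", "Clostridium"),
            genome_length, 112.0, gene_density,
        ),
        GenomeSpec(
            "g_anaerolinea",
            ("root", "Bacteria", "Chloroflexi", "Anaerolineae", "Anaerolineales",
             "Anaerolineaceae", "Anaerolinea"),
            genome_length, 29.0, gene_density,
        ),
        GenomeSpec(
            "g_methanothermobacter",
            ("root", "Archaea", "Euryarchaeota", "Methanobacteria",
             "Methanobacteriales", "Methanobacteriaceae", "Methanothermobacter"),
            genome_length, 8.0, gene_density,
        ),
    )
    return CommunitySpec(
        genomes=genomes, error_rate=error_rate,
        p_nohit=p_nohit, p_offtarget=p_offtarget, seed=seed,
    )
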