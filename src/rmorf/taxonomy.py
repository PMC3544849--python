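"""Lowest-common-ancestor taxonomic binning.

Each ORF carries a set of protein homology hits; after a bit-score floor
and a top-percent filter, the ORF is assigned to the deepest taxonomy
node shared by every retained hit (the conservative LCA rule popularised
by MEGAN).  ORFs whose hits disagree so strongly that the LCA collapses
to a very high rank are flagged as chimeric and discarded, and taxa with
too few assigned ORFs have their ORFs promoted to the nearest ancestor
with enough support, so that no read mass is silently lost.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .io_formats import ProteinHit

#: sentinel taxon for ORFs with no retained hits / no surviving assignment
UNASSIGNED = "unassigned"

#: canonical rank order, root first (gaps along a lineage are allowed)
RANK_ORDER = ("root", "superkingdom", "phylum", "class", "order", "family", "genus")


class TaxonomyTree:
    """Rooted, rank-labelled taxonomy.

    ``nodes`` maps taxon_id -> (parent_id, rank, name).  Exactly one root
    (its parent is itself); no cycles; every node reachable from the
    root; ranks along any root-to-leaf path follow :data:`RANK_ORDER`
    with gaps allowed.
    """

    def __init__(self, nodes: Mapping[str, tuple[str, str, str]], root: str):
        self.nodes = dict(nodes)
        self.root = root
        self._path_cache: dict[str, tuple[str, ...]] = {}
        self._validate()

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "TaxonomyTree":
        """Build from (taxon_id, parent_id, rank, name) rows; empty or
        self-referential parent marks the root."""
        nodes: dict[str, tuple[str, str, str]] = {}
        roots: list[str] = []
        for taxon_id, parent_id, rank, name in rows:
            if not parent_id or parent_id == taxon_id:
                roots.append(taxon_id)
                parent_id = taxon_id
            nodes[taxon_id] = (parent_id, rank, name)
        if len(roots) != 1:
            raise InputError(f"taxonomy must have exactly one root, found {len(roots)}: {roots}")
        return cls(nodes, roots[0])

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise InputError(f"root {self.root!r} not among taxonomy nodes")
        for taxon_id, (parent_id, _rank, _name) in self.nodes.items():
            if taxon_id != self.root and parent_id not in self.nodes:
                raise InputError(f"taxon {taxon_id!r} has orphan parent {parent_id!r}")
        rank_idx = {r: i for i, r in enumerate(RANK_ORDER)}
        for taxon_id in self.nodes:
            path = self.path_to_root(taxon_id)  # raises on cycles
            last = -1
            for node in path:
                rank = self.rank(node)
                if rank in rank_idx:
                    if rank_idx[rank] <= last and node != path[0]:
                        raise InputError(
                            f"rank order violated on path to {taxon_id!r} at {node!r} ({rank})"
                        )
                    last = rank_idx[rank]

    # -- basic accessors ----------------------------------------------------

    def parent(self, taxon_id: str) -> str:
        return self.nodes[taxon_id][0]

    def rank(self, taxon_id: str) -> str:
        return self.nodes[taxon_id][1]

    def name(self, taxon_id: str) -> str:
        return self.nodes[taxon_id][2]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def path_to_root(self, taxon_id: str) -> tuple[str, ...]:
        """Path root -> ... -> taxon_id (root first)."""
        if taxon_id in self._path_cache:
            return self._path_cache[taxon_id]
        if taxon_id not in self.nodes:
            raise InputError(f"unknown taxon {taxon_id!r}")
        path = [taxon_id]
        seen = {taxon_id}
        node = taxon_id
        while node != self.root:
            node = self.parent(node)
            if node in seen:
                raise InputError(f"cycle in taxonomy at {node!r}")
            seen.add(node)
            path.append(node)
        result = tuple(reversed(path))
        self._path_cache[taxon_id] = result
        return result

    def depth(self, taxon_id: str) -> int:
        return len(self.path_to_root(taxon_id)) - 1

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """The ancestor (or the node itself) carrying the given rank, else None."""
        for node in self.path_to_root(taxon_id):
            if self.rank(node) == rank:
                return node
        return None

    def find_by_name(self, name: str) -> str:
        for taxon_id in self.nodes:
            if self.name(taxon_id) == name:
                return taxon_id
        raise KeyError(name)


@dataclass(frozen=True)
class LcaParams:
    """Filter settings for the LCA assignment.

    Defaults pin the MEGAN4-era values: bit-score floor 35, top-percent
    10, min-support 5.  ``discard_rank`` is the rank at or above which an
    assignment counts as discarded-chimeric; the default ``root`` only
    discards ORFs whose hits span the whole tree.
    """

    min_score: float = 35.0
    top_percent: float = 10.0
    min_support: int = 5
    discard_rank: str = "root"

    def __post_init__(self) -> None:
        if not (0 < self.top_percent <= 100):
            raise InputError(f"top_percent must be in (0, 100], got {self.top_percent}")
        if self.min_support < 1:
            raise InputError(f"min_support must be >= 1, got {self.min_support}")


def retain_hits(hits: Sequence[ProteinHit], params: LcaParams) -> list[ProteinHit]:
    """Apply the bit-score floor and the top-percent filter to one ORF's hits."""
    survivors = [h for h in hits if h.bit_score >= params.min_score]
    if not survivors:
        return []
    best = max(h.bit_score for h in survivors)
    floor = (1.0 - params.top_percent / 100.0) * best
    return [h for h in survivors if h.bit_score >= floor]


def lca_of_taxa(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Deepest node lying on every member's root path; empty set -> unassigned."""
    taxa = list(taxa)
    if not taxa:
        return UNASSIGNED
    paths = [tree.path_to_root(t) for t in taxa]
    shortest = min(len(p) for p in paths)
    lca = tree.root
    for i in range(shortest):
        node = paths[0][i]
        if all(p[i] == node for p in paths):
            lca = node
        else:
            break
    return lca


def assign_orf_taxonomy(
    all_hits: Sequence[ProteinHit],
    tree: TaxonomyTree,
    params: LcaParams | None = None,
    min_support_mode: str = "promote",
) -> tuple[dict[str, str], Counter]:
    """LCA-assign every hit-bearing ORF.

    Returns ``(orf_id -> taxon_id, per-taxon ORF counts)``.  ORFs whose
    LCA resolves at or above ``params.discard_rank`` are flagged
    chimeric and mapped to ``unassigned``; afterwards min-support is
    applied (see :func:`apply_min_support`).
    """
    params = params or LcaParams()
    by_orf: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in all_hits:
        if h.subject_taxon not in tree:
            raise InputError(f"hit on {h.orf_id}: subject taxon {h.subject_taxon!r} not in tree")
        by_orf[h.orf_id].append(h)

    rank_idx = {r: i for i, r in enumerate(RANK_ORDER)}
    discard_idx = rank_idx.get(params.discard_rank, 0)

    assignments: dict[str, str] = {}
    for orf_id in sorted(by_orf):
        retained = retain_hits(by_orf[orf_id], params)
        taxa = {h.subject_taxon for h in retained}
        lca = lca_of_taxa(taxa, tree)
        if lca == UNASSIGNED:
            assignments[orf_id] = UNASSIGNED
            continue
        lca_rank = tree.rank(lca)
        # chimeric if the LCA collapsed to discard_rank or any rank above it
        if lca_rank in rank_idx and rank_idx[lca_rank] <= discard_idx:
            assignments[orf_id] = UNASSIGNED
        else:
            assignments[orf_id] = lca

    assignments = apply_min_support(assignments, tree, params.min_support, mode=min_support_mode)
    counts = Counter(assignments.values())
    return assignments, counts


def apply_min_support(
    assignments: Mapping[str, str],
    tree: TaxonomyTree,
    min_support: int,
    mode: str = "promote",
) -> dict[str, str]:
    """Enforce a minimum number of ORFs per reported taxon.

    Taxa with fewer than ``min_support`` directly assigned ORFs have
    their ORFs promoted to the nearest ancestor meeting support
    (``mode='promote'``, the default, conserving read mass) or set to
    unassigned (``mode='drop'``).  If even the root fails support the
    ORFs become unassigned.
    """
    if mode not in ("promote", "drop"):
        raise ValueError(f"mode must be 'promote' or 'drop', got {mode!r}")
    if min_support <= 1:
        return dict(assignments)

    members: dict[str, list[str]] = defaultdict(list)
    for orf_id, taxon in assignments.items():
        members[taxon].append(orf_id)

    result = {o: t for o, t in assignments.items()}
    if mode == "drop":
        for taxon, orf_ids in members.items():
            if taxon != UNASSIGNED and len(orf_ids) < min_support:
                for o in orf_ids:
                    result[o] = UNASSIGNED
        return result

    # Promote whole depth levels bottom-up so sibling taxa pool their
    # counts at the shared ancestor before that ancestor is evaluated.
    holders: dict[str, list[str]] = defaultdict(list)
    for orf_id, taxon in assignments.items():
        if taxon != UNASSIGNED:
            holders[taxon].append(orf_id)
    max_depth = max((tree.depth(t) for t in holders), default=0)
    for depth in range(max_depth, 0, -1):
        for taxon in sorted(t for t in holders if tree.depth(t) == depth):
            if len(holders[taxon]) < min_support:
                holders[tree.parent(taxon)].extend(holders.pop(taxon))
    if tree.root in holders and len(holders[tree.root]) < min_support:
        for orf_id in holders.pop(tree.root):
            result[orf_id] = UNASSIGNED
    for taxon, orf_ids in holders.items():
        for orf_id in orf_ids:
            result[orf_id] = taxon
    return result
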