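"""Carbohydrate-active gene screening from protein-domain hits.

Domain hits (Pfam-scan style) are screened against a Pfam-to-CAZy
mapping restricted to families with an unambiguous Pfam model: an ORF
with at least one retained glycoside-hydrolase (GH) or
carbohydrate-binding-module (CBM) hit below the E-value cutoff is a
candidate carbohydrate-active gene.  Modules are counted per retained
hit — complete ORFs and ORF fragments alike, with no within-ORF
deduplication by default — and families roll up into functional
categories (cellulase, endohemicellulase, debranching,
oligosaccharide-degrading, binding).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .io_formats import DomainHit, _rows

FAMILY_CLASSES = ("GH", "CBM")
CATEGORIES = (
    "cellulase", "endohemicellulase", "debranching",
    "oligosaccharide-degrading", "binding", "other",
)

#: default screening cutoff for domain hits
DOMAIN_EVALUE_CUTOFF = 1e-4


@dataclass(frozen=True)
class CazyMapEntry:
    """One Pfam accession mapped to exactly one CAZy family."""

    domain_acc: str
    cazy_family: str
    family_class: str
    category: str

    def __post_init__(self) -> None:
        if self.family_class not in FAMILY_CLASSES:
            raise InputError(f"unknown family class {self.family_class!r} for {self.domain_acc}")
        if self.category not in CATEGORIES:
            raise InputError(f"unknown category {self.category!r} for {self.domain_acc}")


@dataclass
class CazyAnnotation:
    """Per-ORF screening outcome: retained modules and candidate status."""

    orf_id: str
    modules: list[tuple[str, str, float]]   # (cazy_family, domain_acc, evalue)

    @property
    def is_candidate_gene(self) -> bool:
        return bool(self.modules)


def load_cazy_map(path: str | Path | None = None) -> list[CazyMapEntry]:
    """Load a Pfam-to-CAZy TSV (domain_acc, cazy_family, family_class, category).

    A Pfam accession mapping to two different families violates the
    clear-model rule and is a hard error.  With no path, the packaged
    curated map is used.
    """
    if path is None:
        ref = resources.files("rmorf").joinpath("data/cazy_map.tsv")
        with resources.as_file(ref) as p:
            return load_cazy_map(p)
    entries: list[CazyMapEntry] = []
    seen: dict[str, str] = {}
    for lineno, cols in _rows(path):
        if len(cols) != 4:
            raise InputError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
        acc, family, fclass, category = cols
        if acc in seen:
            if seen[acc] != family:
                raise InputError(
                    f"{path}:{lineno}: {acc} maps to both {seen[acc]} and {family} "
                    "(violates the one-family-per-Pfam rule)"
                )
            continue
        seen[acc] = family
        entries.append(CazyMapEntry(acc, family, fclass, category))
    return entries


def screen_domain_hits(
    hits: Sequence[DomainHit],
    cazy_map: Sequence[CazyMapEntry],
    evalue_cutoff: float = DOMAIN_EVALUE_CUTOFF,
    merge_overlaps: bool = False,
) -> tuple[list[CazyAnnotation], Counter]:
    """Screen hits against the map at the E-value cutoff.

    Returns per-ORF annotations (candidate genes = ORFs with >= 1
    retained hit) and module counts per family.  By default every
    retained hit counts as one module — complete ORFs and fragments
    alike, with no within-ORF deduplication.  With ``merge_overlaps``,
    same-family hits on one ORF whose residue intervals overlap by at
    least half the shorter interval collapse into a single module.
    """
    by_acc = {e.domain_acc: e for e in cazy_map}
    retained: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        entry = by_acc.get(h.domain_acc)
        if entry is None or h.evalue > evalue_cutoff:
            continue
        retained.setdefault((h.orf_id, entry.cazy_family), []).append(h)

    per_orf: dict[str, CazyAnnotation] = {}
    family_counts: Counter = Counter()
    for (orf_id, family), group in retained.items():
        if merge_overlaps:
            group = _merge_overlapping(group)
        ann = per_orf.setdefault(orf_id, CazyAnnotation(orf_id=orf_id, modules=[]))
        for h in group:
            ann.modules.append((family, h.domain_acc, h.evalue))
            family_counts[family] += 1
    annotations = [per_orf[k] for k in sorted(per_orf)]
    for ann in annotations:
        ann.modules.sort()
    return annotations, family_counts


def _merge_overlapping(group: list[DomainHit], min_frac: float = 0.5) -> list[DomainHit]:
    """Greedy merge of hits whose intervals overlap >= min_frac of the shorter."""
    kept: list[DomainHit] = []
    for h in sorted(group, key=lambda h: (h.evalue, h.ali_from)):
        for k in kept:
            ov = min(h.ali_to, k.ali_to) - max(h.ali_from, k.ali_from) + 1
            shorter = min(h.ali_to - h.ali_from, k.ali_to - k.ali_from) + 1
            if ov >= min_frac * shorter:
                break
        else:
            kept.append(h)
    return kept


def rollup_categories(
    family_counts: Mapping[str, int],
    cazy_map: Sequence[CazyMapEntry],
) -> tuple[dict[str, int], dict[str, float], dict[str, float]]:
    """Roll module counts per family into functional-category totals.

    Returns ``(category_counts, gh_proportions, cbm_proportions)`` where
    the proportions are per-family shares of the GH total and CBM total
    respectively.  A counted family missing from the map is an error.
    """
    fam_info: dict[str, tuple[str, str]] = {}
    for e in cazy_map:
        fam_info.setdefault(e.cazy_family, (e.family_class, e.category))
    category_counts: dict[str, int] = {}
    gh_total = cbm_total = 0
    for family, count in family_counts.items():
        if family not in fam_info:
            raise InputError(f"family {family!r} not present in the CAZy map")
        fclass, category = fam_info[family]
        category_counts[category] = category_counts.get(category, 0) + count
        if fclass == "GH":
            gh_total += count
        else:
            cbm_total += count
    gh_props = {
        f: c / gh_total for f, c in sorted(family_counts.items())
        if fam_info[f][0] == "GH" and gh_total > 0
    }
    cbm_props = {
        f: c / cbm_total for f, c in sorted(family_counts.items())
        if fam_info[f][0] == "CBM" and cbm_total > 0
    }
    return category_counts, gh_props, cbm_props


def identity_histogram(
    best_identities: Mapping[str, float], bin_width: int = 10
) -> dict[tuple[int, int], int]:
    """Histogram of best-hit identity percentages.

    Bins are half-open [0,10), ..., with the top bin closed at 100.
    Counts conserve the input size; out-of-range identities error.
    """
    if not (0 < bin_width <= 100) or 100 % bin_width != 0:
        raise InputError(f"bin_width must divide 100, got {bin_width}")
    edges = list(range(0, 101, bin_width))
    counts = {(lo, lo + bin_width): 0 for lo in edges[:-1]}
    for orf_id, ident in best_identities.items():
        if not (0 <= ident <= 100):
            raise InputError(f"{orf_id}: identity {ident} outside [0, 100]")
        idx = min(int(ident // bin_width), len(edges) - 2)
        lo = edges[idx]
        counts[(lo, lo + bin_width)] += 1
    return counts


def best_identity_per_orf(hits) -> dict[str, float]:
    """The identity of each ORF's best-scoring protein hit (for the histogram)."""
    best: dict[str, tuple[float, float]] = {}
    for h in hits:
        cur = best.get(h.orf_id)
        if cur is None or h.bit_score > cur[0]:
            best[h.orf_id] = (h.bit_score, h.identity_pct)
    return {o: ident for o, (_s, ident) in best.items()}


def write_family_table(path, family_counts: Mapping[str, int],
                       annotations: Sequence[CazyAnnotation],
                       cazy_map: Sequence[CazyMapEntry]) -> None:
    """TSV: family, class, category, modules, genes."""
    fam_info = {e.cazy_family: (e.family_class, e.category) for e in cazy_map}
    genes_per_family: Counter = Counter()
    for ann in annotations:
        for fam in {m[0] for m in ann.modules}:
            genes_per_family[fam] += 1
    with open(path, "w") as fh:
        fh.write("# family\tclass\tcategory\tmodules\tgenes\n")
        for fam in sorted(family_counts):
            fclass, cat = fam_info[fam]
            fh.write(f"{fam}\t{fclass}\t{cat}\t{family_counts[fam]}\t{genes_per_family[fam]}\n")
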