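"""Read-weighted versus ORF-count community profiling, and rarefaction.

Counting annotated ORFs ignores how deeply each ORF is covered, so in a
community with scattered coverage the ORF-count profile misrepresents
abundance; weighting each ORF's taxon by its mapped read count (the
RMORF correction) recovers the underlying abundance structure.  This
module builds both profiles at a chosen rank, quantifies their
discordance, and computes rarefaction curves with a closed-form
hypergeometric expectation available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import InputError
from .taxonomy import UNASSIGNED, TaxonomyTree


@dataclass
class TaxProfile:
    """Weighted taxon composition at one rank.

    ``weights`` covers assigned taxa only; unassigned mass is reported
    separately as ``total_input - total_assigned`` rather than silently
    renormalised away.
    """

    rank: str
    weights: dict[str, float]
    unit: str                      # "reads" or "orfs"
    total_assigned: float
    total_input: float

    @property
    def proportions(self) -> dict[str, float]:
        if self.total_assigned == 0:
            return {}
        return {t: w / self.total_assigned for t, w in self.weights.items()}

    @property
    def unassigned_fraction(self) -> float:
        if self.total_input == 0:
            return 0.0
        return (self.total_input - self.total_assigned) / self.total_input


def _project(taxon: str, tree: TaxonomyTree, rank: str) -> str:
    if taxon == UNASSIGNED or taxon not in tree:
        return UNASSIGNED
    at_rank = tree.ancestor_at_rank(taxon, rank)
    return at_rank if at_rank is not None else UNASSIGNED


def read_weighted_profile(
    orf_taxa: Mapping[str, str],
    counts: Mapping[str, int],
    tree: TaxonomyTree,
    rank: str = "phylum",
) -> TaxProfile:
    """Profile where each taxon's weight is the sum of mapped reads over its ORFs."""
    weights: dict[str, float] = {}
    total_input = float(sum(counts.values()))
    assigned = 0.0
    for orf_id, n in counts.items():
        taxon = _project(orf_taxa.get(orf_id, UNASSIGNED), tree, rank)
        if taxon == UNASSIGNED:
            continue
        weights[taxon] = weights.get(taxon, 0.0) + n
        assigned += n
    return TaxProfile(rank=rank, weights=weights, unit="reads",
                      total_assigned=assigned, total_input=total_input)


def orf_count_profile(
    orf_taxa: Mapping[str, str],
    tree: TaxonomyTree,
    rank: str = "phylum",
) -> TaxProfile:
    """Profile where each taxon's weight is its number of annotated ORFs."""
    weights: dict[str, float] = {}
    assigned = 0.0
    for orf_id, taxon in orf_taxa.items():
        at_rank = _project(taxon, tree, rank)
        if at_rank == UNASSIGNED:
            continue
        weights[at_rank] = weights.get(at_rank, 0.0) + 1
        assigned += 1
    return TaxProfile(rank=rank, weights=weights, unit="orfs",
                      total_assigned=assigned, total_input=float(len(orf_taxa)))


def profile_correlation(p: TaxProfile, q: TaxProfile, method: str = "pearson") -> float:
    """Correlation of two profiles' proportion vectors over the taxon union.

    Absent taxa are zero-filled.  Fewer than 3 union taxa, or a
    zero-variance vector (e.g. a uniform profile), is an error: the
    coefficient would be degenerate.
    """
    if p.rank != q.rank:
        raise InputError(f"profiles are at different ranks: {p.rank} vs {q.rank}")
    taxa = sorted(set(p.proportions) | set(q.proportions))
    if len(taxa) < 3:
        raise InputError(f"correlation needs >= 3 taxa in the union, got {len(taxa)}")
    vp = np.array([p.proportions.get(t, 0.0) for t in taxa])
    vq = np.array([q.proportions.get(t, 0.0) for t in taxa])
    if np.allclose(vp, vp[0]) or np.allclose(vq, vq[0]):
        raise InputError("correlation undefined: a profile has zero variance over the union")
    if method == "pearson":
        return float(stats.pearsonr(vp, vq).statistic)
    if method == "spearman":
        return float(stats.spearmanr(vp, vq).statistic)
    raise InputError(f"unknown correlation method {method!r}")


def report_filter(
    orf_profile: TaxProfile,
    read_profile: TaxProfile,
    min_orfs: int = 5,
    min_reads: int = 1000,
) -> list[str]:
    """Taxa meeting both reporting thresholds (display rule for summary figures)."""
    return sorted(
        t for t in set(orf_profile.weights) & set(read_profile.weights)
        if orf_profile.weights[t] > min_orfs and read_profile.weights[t] > min_reads
    )


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction_curve(
    unit_labels: Sequence[str],
    depths: Sequence[int],
    reps: int = 100,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Monte-Carlo rarefaction: for each depth m, the mean (and sd) over
    ``reps`` without-replacement subsamples of the number of distinct labels."""
    labels = np.asarray(unit_labels, dtype=object)
    N = labels.size
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[float, float]] = {}
    for m in depths:
        if m < 1 or m > N:
            raise InputError(f"depth {m} outside [1, {N}]")
        richness = np.empty(reps)
        for r in range(reps):
            sub = rng.choice(labels, size=m, replace=False)
            richness[r] = len(set(sub.tolist()))
        out[int(m)] = (float(richness.mean()), float(richness.std(ddof=1) if reps > 1 else 0.0))
    return out


def expected_richness(unit_labels: Sequence[str], m: int) -> float:
    """Closed-form expected distinct labels in a without-replacement
    subsample of size m: sum_i [1 - C(N-N_i, m) / C(N, m)]."""
    labels, counts = np.unique(np.asarray(unit_labels, dtype=object), return_counts=True)
    N = int(counts.sum())
    if m < 1 or m > N:
        raise InputError(f"depth {m} outside [1, {N}]")

    def log_comb(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -np.inf
        return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))

    total = 0.0
    denom = log_comb(N, m)
    for c in counts:
        num = log_comb(N - int(c), m)
        total += 1.0 - (np.exp(num - denom) if np.isfinite(num) else 0.0)
    return total


def default_depths(N: int, n_depths: int = 10) -> list[int]:
    """n_depths evenly spaced subsample sizes from N/n_depths up to N."""
    return sorted({max(1, int(round(N * (i + 1) / n_depths))) for i in range(n_depths)})
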