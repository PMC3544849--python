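"""Decompose a reads-per-ORF cloud into coverage trends.

ORFs from genomes at similar abundance fall on a line through the
origin in the (ORF length, read count) plane; slope x read length is
their fold coverage.  Here we simulate Poisson read counts for three
abundance tiers and let BIC choose the number of trends.
"""

import numpy as np

from rmorf import OrfCoveragePoint, select_num_trends, trend_taxonomy_summary

rng = np.random.default_rng(0)
points, taxa = [], {}
for coverage, phylum in ((112.0, "Firmicutes"), (29.0, "Chloroflexi"), (8.0, "Euryarchaeota")):
    lengths = rng.integers(300, 3001, size=500)
    counts = rng.poisson(coverage * lengths / 100)
    for i, (L, n) in enumerate(zip(lengths, counts)):
        p = OrfCoveragePoint.make(f"{phylum}_{i}", int(L), int(n), r=100)
        points.append(p)
        taxa[p.orf_id] = phylum

model = select_num_trends(points, seed=0)
print(f"BIC selected K = {model.K} trends (BIC {model.bic:.1f})")
for k in range(model.K):
    print(f"  trend {k + 1}: slope {model.slopes[k]:.3f} reads/nt "
          f"-> {model.coverages[k]:.1f}x fold coverage, weight {model.weights[k]:.2f}")

# per-trend taxonomy: each trend should be dominated by its generating phylum
summary = trend_taxonomy_summary(model, taxa)
for k, comp in summary.items():
    top = max(comp, key=comp.get)
    print(f"  trend {k + 1} composition: {top} {comp[top]:.1%}")
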