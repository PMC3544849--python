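# Methods

## The quantification problem

For an assembled metagenome, community composition can be estimated
either from annotated reads (low annotation efficiency for 100 bp
reads) or from annotated ORFs (ignores coverage, so abundant genomes
are under-weighted). `rmorf` implements the combined route: annotate
ORFs, map the reads back onto the ORFs, and weight each ORF's taxon by
its mapped read count. All modules assume an enriched, low-complexity
community in which member genomes occupy a few well-separated
abundance tiers.

## Read-to-ORF mapping

Contract: each read is placed ungapped at the offset — over every ORF,
every offset, both strands — with the fewest mismatches; it is kept
only if that minimum is ≤ `max_mismatches` (default 2, over the whole
read). `N` never matches. Ties are broken by (ORF id lexicographic,
smallest offset, `+` strand), replacing an external aligner's
unspecified internal tie behaviour with a reproducible rule. Mates of
a pair are counted as two independent reads, and reads that overlap an
ORF boundary on the source contig simply fail to map to the ORF.

The implementation is a pigeonhole seed index: a read with at most *m*
mismatches must contain one of *m*+1 disjoint exact segments, so
looking those segments up in a k-mer position table (k = ⌊read
length/(m+1)⌋) and verifying each candidate offset finds exactly the
winners of the full scan whenever the best alignment is within the
mismatch budget. The exhaustive all-offset scan is retained in the test
suite as an independent oracle. SAM from any external aligner can be
substituted; records without an NM tag are accepted as 0 mismatches
with a warning.

## Coverage-trend decomposition

Per-ORF fold coverage is ĉ = n·r/L (n mapped reads of length r on an
ORF of length L; r defaults to 100 nt). ORFs with n = 0 are excluded
from fitting (log undefined) and reported separately.

The trends are modelled as a K-component mixture on x = log ĉ with
component density N(x; μ_k, σ_k² + v_i), where v_i = 1/n_i is the
known counting-noise variance of log ĉ for Poisson read counts, and
σ_k is the component's *excess* dispersion. Carrying v_i explicitly
matters: without it, the within-tier spread of x is a scale mixture
(short ORFs are noisier than long ones) and BIC inflates K to mimic
that shape — measured on three-tier simulations, a plain Gaussian
mixture selects K = 4–5 essentially always, while the noise-aware
mixture selects K = 3 in 20/20 seeds with ~0.1% coverage error.

Fitting is EM: responsibilities under the total variance σ_k² + v_i;
M-step by coordinate ascent (precision-weighted mean for μ_k, a
fixed-point reweighting update for σ_k² accepted only when it improves
the Q-function), which keeps the observed log-likelihood monotone —
asserted at every iteration. Initialisation at K evenly spaced
quantiles of x, 5 restarts (jittered after the first), convergence at
relative log-likelihood improvement < 1e-8, iteration cap 300 (a
warning is issued and the best iterate returned when the cap is hit —
this happens for overfit K whose surplus components wander without
affecting selection), variance floor 1e-6.

After EM, each component's slope is re-estimated as the
origin-constrained weighted least-squares slope Σγ·n·L / Σγ·L² over
its responsibilities γ, and its fold coverage is slope × r — the
"lines through the origin" view of the same fit. Membership is argmax
responsibility; components are sorted by decreasing coverage.

K is selected by BIC = −2·loglik + (3K−1)·ln N over K = 1..5. Three
tiers is an empirical outcome of the data, not a constant. Fewer than
10 nonzero points caps K at 1 with a warning.

Known limitation: when reads are mapped to ORFs rather than contigs,
edge loss (reads overhanging the ORF ends) depresses ĉ by a factor of
roughly (L−r)/L, which spreads each tier downward in a
length-dependent way; with very short ORFs this inflates within-tier
dispersion beyond the counting-noise term. The estimator absorbs this
in σ_k on desk-scale runs, but recovered coverages from fully mapped
(rather than Poisson-simulated) counts sit a few percent below the
generating values.

## LCA taxonomic binning

Per ORF: drop hits below the bit-score floor, keep hits within
`top_percent` of the best surviving score, and assign the deepest
taxonomy node on every retained hit's root path. Defaults pin the
MEGAN4-era values min_score = 35, top_percent = 10, min_support = 5;
the homology table itself is pre-filtered at E ≤ 1e-5 on read-in. All
are overridable — the defaults are documented assumptions, not
recorded values.

Chimera rule: an ORF whose LCA collapses to `discard_rank` or above is
flagged discarded-chimeric. The default `discard_rank="root"` only
discards ORFs whose hits span the entire tree (e.g. both
superkingdoms); a stricter rank can be configured.

Min-support: taxa with fewer than `min_support` assigned ORFs have
their ORFs promoted to the nearest ancestor meeting support, processed
level by level from the deepest taxa so sibling taxa pool their counts
at the shared ancestor before it is evaluated; if even the root fails,
the ORFs become unassigned. Promotion (rather than deletion) conserves
read mass; a `drop` mode is available. ORF-count and read-count
reporting thresholds (the "over 5 ORFs and 1000 reads" display style)
are exposed as independent filters on profiles.

## Profiles, correlation, rarefaction

Profiles project each ORF's taxon to the requested rank (ancestor at
that rank, else unassigned) and weight it by mapped reads
(`read_weighted_profile`) or by 1 (`orf_count_profile`). Unassigned
mass is reported separately, never silently renormalised.
`profile_correlation` is Pearson (Spearman optional) on zero-filled
proportion vectors over the taxon union; fewer than 3 union taxa or a
zero-variance vector is an error rather than a NaN.

Rarefaction subsamples classified units without replacement (default
10 evenly spaced depths to N, 100 replicates, seeded) and reports mean
distinct taxa per depth; the closed form E[S_m] = Σ_i [1 −
C(N−N_i,m)/C(N,m)] is computed alongside (log-gamma arithmetic) and
used as the calibration oracle in tests.

## Synthetic community generator

The generator emulates an enriched thermophilic cellulolytic sludge:
the packaged three-tier preset places one genome per tier at 112× /
29× / 8× fold coverage labelled Firmicutes/Clostridium,
Chloroflexi/Anaerolinea and Euryarchaeota/Methanothermobacter, each
50 kb at 0.5 ORFs/kb (desk-scale sizes chosen so a full pipeline run
takes seconds), read length 100 bp, substitution error rate 0.002,
and a 12.8% probability per ORF of carrying no homology evidence —
the taxonomically dark fraction reported for such communities.
Tiers are internally uniform; no per-genome abundance distribution
within a tier is modelled.

Genomes are iid random ACGT; ORFs are non-overlapping intervals with
lengths uniform on [300, 3000] nt (multiples of 3), placed by
distributing the leftover slack uniformly among gaps. Reads are drawn
per genome as round(coverage × length / read length) split into pairs,
fragments Normal(180, 20) nt clipped to feasible sizes, both strands,
substitution-only errors (the downstream mapping contract is ungapped,
so indels would only create unmappable reads). Homology hits give the
true taxon the top bit score; off-target hits (probability
`p_offtarget` each) point to a random other genus with scores at least
15% below the top, so default top-percent filtering separates them —
the gap is configurable, and shrinking it below the top-percent window
is the intended way to stress the LCA. Identity percentages follow
20 + 80·Beta(1, 1.4) (median ≈ 51%) so identity histograms exercise
the full 20–100% range with half the mass below 50%. Domain hits mark
each ORF carbohydrate-active with probability `p_cazy`, draw 1–3
families from configurable weights with sub-cutoff E-values, and add a
decoy fraction (non-CAZy accessions or over-cutoff E-values) that the
screen must reject. Truth tables accompany every artifact.

What passing on this generator does and does not show: it validates
the estimators' correctness and calibration under the stated
statistical structure (separated tiers, substitution errors,
well-behaved hit scores). Real data add chimeric contigs, conserved
cross-taxon genes, uneven within-genome coverage, indels and database
bias, none of which are modelled; results on real communities depend
on those factors in ways these tests cannot certify.

## CAZy screening

Domain hits are kept when E ≤ 1e-4 and the accession appears in the
Pfam↔CAZy map; the packaged map is a curated table of real Pfam
accessions for the GH/CBM families characteristic of cellulolytic
communities (GH1–GH78, CBM2/3/6/20/25), restricted to one CAZy family
per accession, with functional categories (cellulase,
endohemicellulase, debranching, oligosaccharide-degrading, binding).
It is data, not code, and user-replaceable. Modules are counted per
retained hit with no within-ORF deduplication (complete ORFs and
fragments alike); an optional overlap-merge (≥ 50% residue overlap
within a family) exists but is off by default. Candidate genes are
distinct ORFs with ≥ 1 retained hit. The identity histogram uses the
best-scoring hit per ORF, half-open decade bins with the top bin
closed at 100%.

## Numerical and degenerate-input choices

- All randomness flows through numpy generators derived from one seed
  (per-stage sub-seeds via hashing in the pipeline; identical config +
  seed ⇒ byte-identical outputs, checksummed in the run manifest).
- Empty hit sets, empty profiles, empty trends and zero-count ORFs are
  defined results, not errors; malformed files, unknown identifiers,
  cycles and conflicting map rows are hard errors with the offending
  line named.
- Problem sizes in tests and the acceptance script (500–2,400 ORFs per
  trend fit, ~60–75k reads per end-to-end run, 1,000-instance oracle
  sweeps) are the package's own desk-scale choices; all estimators
  accept arbitrarily larger inputs.
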