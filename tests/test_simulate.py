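"""Synthetic community generator: determinism, coverage, labelled hit tables."""

import numpy as np
import pytest

from rmorf.cazy import load_cazy_map, screen_domain_hits
from rmorf.errors import InputError
from rmorf.simulate import (
    CommunitySpec,
    GenomeSpec,
    build_community,
    fig1_preset,
    revcomp,
    simulate_domain_hits,
    simulate_orf_reads,
    simulate_protein_hits,
    simulate_reads,
)
from rmorf.taxonomy import LcaParams, assign_orf_taxonomy


def one_genome_spec(length=10_000, density=1.0, coverage=10.0, seed=0, **kw):
    return CommunitySpec(
        genomes=(GenomeSpec("g1", ("root", "Bacteria", "Firmicutes"), length, coverage, density),),
        seed=seed,
        **kw,
    )


class TestBuildCommunity:
    def test_orf_count_and_lineage(self):
        comm = build_community(one_genome_spec(length=10_000, density=1.0))
        assert len(comm.orfs) == 10
        assert all(comm.truth[o.orf_id] == "Firmicutes" for o in comm.orfs)

    def test_orfs_non_overlapping_and_in_range(self):
        comm = build_community(one_genome_spec(length=30_000, density=0.8, seed=5))
        intervals = sorted((o.start, o.end) for o in comm.orfs)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2
        for o in comm.orfs:
            assert 300 <= o.length_nt <= 3000 and o.length_nt % 3 == 0

    def test_determinism_same_spec_same_output(self):
        spec = one_genome_spec(seed=11)
        c1, c2 = build_community(spec), build_community(spec)
        assert c1.genomes == c2.genomes
        assert c1.orfs == c2.orfs
        assert c1.orf_seqs == c2.orf_seqs

    def test_infeasible_density_errors(self):
        with pytest.raises(InputError, match="infeasible"):
            build_community(one_genome_spec(length=1_000, density=1000.0))

    def test_minus_strand_orf_seq_is_revcomp(self):
        comm = build_community(one_genome_spec(seed=3))
        minus = [o for o in comm.orfs if o.strand == "-"]
        assert minus, "expected at least one minus-strand ORF"
        o = minus[0]
        genome = comm.genomes[o.contig_id]
        assert comm.orf_seqs[o.orf_id] == revcomp(genome[o.start:o.end])


class TestSimulateReads:
    def test_read_count_arithmetic(self):
        comm = build_community(one_genome_spec(length=10_000, coverage=10.0))
        r1, r2, _ = simulate_reads(comm)
        assert len(r1) == len(r2) == 500  # 10x * 10,000 / 100 = 1,000 reads

    def test_error_free_reads_are_genome_substrings(self):
        comm = build_community(one_genome_spec(length=5_000, coverage=2.0, density=0.3))
        r1, r2, _ = simulate_reads(comm)
        genome = comm.genomes["g1"]
        for rid, seq, _q in r1 + r2:
            assert seq in genome or revcomp(seq) in genome

    def test_mate_ids_pair_up(self):
        comm = build_community(one_genome_spec(length=5_000, coverage=1.0, density=0.3))
        r1, r2, _ = simulate_reads(comm)
        for (id1, _s1, _q1), (id2, _s2, _q2) in zip(r1, r2):
            assert id1.endswith("/1") and id2.endswith("/2")
            assert id1[:-2] == id2[:-2]

    def test_mean_depth_matches_target(self):
        """Brute-force per-base depth from true read positions ~ target coverage."""
        for seed in (1, 2, 3):
            spec = one_genome_spec(length=50_000, coverage=20.0, density=0.2, seed=seed)
            comm = build_community(spec)
            _r1, _r2, truth = simulate_reads(comm)
            depth = np.zeros(50_000)
            for t in truth:
                depth[t.start:t.end] += 1
            assert abs(depth.mean() - 20.0) < 2.0


class TestProteinHits:
    def test_p_nohit_one_gives_empty_table(self):
        spec = one_genome_spec(p_nohit=1.0)
        comm = build_community(spec)
        assert simulate_protein_hits(comm) == []

    def test_no_offtarget_lca_recovers_truth(self):
        spec = fig1_preset(seed=5, genome_length=20_000, p_nohit=0.0, p_offtarget=0.0)
        comm = build_community(spec)
        hits = simulate_protein_hits(comm)
        assignments, _ = assign_orf_taxonomy(hits, comm.tree, LcaParams(min_support=1))
        assert assignments == comm.truth

    def test_unassigned_fraction_calibrated(self):
        """p_nohit = 0.128 over 10,000 ORFs leaves 12.8% +- 1% without hits."""
        spec = CommunitySpec(
            genomes=tuple(
                GenomeSpec(f"g{i}", ("root", "Bacteria", "Firmicutes"), 500_000, 5.0, 1.0)
                for i in range(20)
            ),
            p_nohit=0.128,
            seed=17,
            orf_length_range=(300, 600),
        )
        comm = build_community(spec)
        assert len(comm.orfs) == 10_000
        hits = simulate_protein_hits(comm)
        with_hits = {h.orf_id for h in hits}
        frac = 1.0 - len(with_hits) / len(comm.orfs)
        assert abs(frac - 0.128) < 0.01

    def test_offtarget_scores_stay_below_top_percent_window(self):
        spec = fig1_preset(seed=9, genome_length=20_000, p_nohit=0.0, p_offtarget=0.5)
        comm = build_community(spec)
        hits = simulate_protein_hits(comm)
        by_orf = {}
        for h in hits:
            by_orf.setdefault(h.orf_id, []).append(h)
        for orf_id, orf_hits in by_orf.items():
            top = max(h.bit_score for h in orf_hits)
            for h in orf_hits:
                if h.subject_taxon != comm.truth[orf_id]:
                    assert h.bit_score <= 0.85 * top + 0.1


class TestDomainHits:
    def test_p_cazy_zero_yields_no_candidates(self, tiny_community):
        cmap = load_cazy_map()
        hits, truth = simulate_domain_hits(tiny_community.orfs, cmap, p_cazy=0.0, seed=1)
        assert truth == {}
        anns, counts = screen_domain_hits(hits, cmap)
        assert anns == [] and sum(counts.values()) == 0

    def test_concentrated_weights_dominate_counts(self, tiny_community):
        cmap = load_cazy_map()
        hits, _ = simulate_domain_hits(
            tiny_community.orfs, cmap, p_cazy=0.9,
            family_weights={"GH9": 10.0, "CBM3": 10.0, "GH2": 0.5},
            seed=4,
        )
        _, counts = screen_domain_hits(hits, cmap)
        top2 = {f for f, _c in counts.most_common(2)}
        assert top2 == {"GH9", "CBM3"}

    def test_candidate_count_equals_truth_enumeration(self, tiny_community):
        cmap = load_cazy_map()
        hits, truth = simulate_domain_hits(tiny_community.orfs, cmap, p_cazy=0.3, seed=8)
        anns, _ = screen_domain_hits(hits, cmap)
        # every ORF given a genuine sub-cutoff CAZy hit, and only those,
        # must come out as a candidate gene
        assert {a.orf_id for a in anns if a.is_candidate_gene} == set(truth)

    def test_unknown_weight_family_errors(self, tiny_community):
        with pytest.raises(InputError, match="absent from the map"):
            simulate_domain_hits(tiny_community.orfs, load_cazy_map(),
                                 family_weights={"GH999": 1.0})


class TestOrfReads:
    def test_reads_trace_back_to_source_orf(self, tiny_community):
        reads, source = simulate_orf_reads(tiny_community.orf_seqs, 50, seed=2)
        for rid, seq in reads:
            src = tiny_community.orf_seqs[source[rid]]
            assert seq in src or revcomp(seq) in src


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw", [{"error_rate": 0.5}, {"p_nohit": 1.5}, {"p_offtarget": -0.1}]
    )
    def test_bad_rates_rejected(self, kw):
        with pytest.raises(InputError):
            one_genome_spec(**kw)

    def test_mixed_roots_rejected(self):
        with pytest.raises(InputError, match="single root"):
            CommunitySpec(
                genomes=(
                    GenomeSpec("a", ("rootA", "Bacteria"), 1000, 1.0),
                    GenomeSpec("b", ("rootB", "Bacteria2"), 1000, 1.0),
                )
            )
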