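"""CAZy screening: map loading, E-value screen, category rollup, identity bins."""

import numpy as np
import pytest

from rmorf.cazy import (
    best_identity_per_orf,
    identity_histogram,
    load_cazy_map,
    rollup_categories,
    screen_domain_hits,
)
from rmorf.errors import InputError
from rmorf.io_formats import DomainHit, ProteinHit


def _hit(orf="o1", acc="PF00759", ev=1e-6):
    return DomainHit(orf_id=orf, domain_acc=acc, evalue=ev, score=50.0,
                     ali_from=1, ali_to=100)


def random_hits(rng, n, accs):
    return [
        _hit(orf=f"o{int(rng.integers(0, 40))}",
             acc=accs[int(rng.integers(0, len(accs)))],
             ev=float(10.0 ** -rng.uniform(0.0, 12.0)))
        for _ in range(n)
    ]


class TestLoadMap:
    def test_packaged_map_loads(self):
        entries = load_cazy_map()
        accs = [e.domain_acc for e in entries]
        assert len(accs) == len(set(accs))
        families = {e.cazy_family for e in entries}
        assert {"GH9", "CBM3", "GH2", "GH3"} <= families

    def test_single_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("PF_X\tGH5\tGH\tcellulase\n")
        entries = load_cazy_map(p)
        assert len(entries) == 1 and entries[0].cazy_family == "GH5"

    def test_conflicting_family_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("PF_X\tGH5\tGH\tcellulase\nPF_X\tGH6\tGH\tcellulase\n")
        with pytest.raises(InputError, match="one-family-per-Pfam"):
            load_cazy_map(p)

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("PF_X\tGH5\tZZ\tcellulase\n")
        with pytest.raises(InputError, match="family class"):
            load_cazy_map(p)

    def test_empty_map_screens_to_zero(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("# empty\n")
        anns, counts = screen_domain_hits([_hit()], load_cazy_map(p))
        assert anns == [] and sum(counts.values()) == 0


class TestScreen:
    def test_one_sub_cutoff_hit_one_candidate(self):
        anns, counts = screen_domain_hits([_hit(ev=1e-6)], load_cazy_map())
        assert len(anns) == 1 and anns[0].is_candidate_gene
        assert counts == {"GH9": 1}

    def test_over_cutoff_hit_excluded(self):
        anns, counts = screen_domain_hits([_hit(ev=1e-3)], load_cazy_map(), 1e-4)
        assert anns == [] and sum(counts.values()) == 0

    def test_gh_plus_cbm_is_one_gene_two_modules(self):
        hits = [_hit(acc="PF00759"), _hit(acc="PF00942")]  # GH9 + CBM3
        anns, counts = screen_domain_hits(hits, load_cazy_map())
        assert len(anns) == 1
        assert len(anns[0].modules) == 2
        assert counts == {"GH9": 1, "CBM3": 1}

    def test_filter_monotone_in_cutoff(self):
        rng = np.random.default_rng(11)
        accs = [e.domain_acc for e in load_cazy_map()]
        hits = random_hits(rng, 300, accs)
        prev_genes = prev_modules = -1
        for cutoff in (1e-8, 1e-6, 1e-4, 1e-2, 1.0):
            anns, counts = screen_domain_hits(hits, load_cazy_map(), cutoff)
            genes, modules = len(anns), sum(counts.values())
            assert genes >= prev_genes and modules >= prev_modules
            prev_genes, prev_modules = genes, modules

    def test_conservation_and_order_independence(self):
        rng = np.random.default_rng(13)
        accs = [e.domain_acc for e in load_cazy_map()] + ["PF99999"]
        hits = random_hits(rng, 200, accs)
        cmap = load_cazy_map()
        anns, counts = screen_domain_hits(hits, cmap)
        assert sum(counts.values()) == sum(len(a.modules) for a in anns)
        shuffled = [hits[i] for i in rng.permutation(len(hits))]
        anns2, counts2 = screen_domain_hits(shuffled, cmap)
        assert counts2 == counts
        assert {a.orf_id: sorted(a.modules) for a in anns} == \
               {a.orf_id: sorted(a.modules) for a in anns2}


class TestOverlapMerge:
    def test_overlapping_same_family_hits_collapse(self):
        hits = [
            DomainHit("o1", "PF00759", 1e-10, 80.0, 10, 200),
            DomainHit("o1", "PF00759", 1e-8, 60.0, 50, 210),   # >= 50% overlap
            DomainHit("o1", "PF00759", 1e-7, 50.0, 300, 450),  # disjoint: stays
        ]
        cmap = load_cazy_map()
        _, default_counts = screen_domain_hits(hits, cmap)
        assert default_counts["GH9"] == 3  # fragments counted individually
        _, merged_counts = screen_domain_hits(hits, cmap, merge_overlaps=True)
        assert merged_counts["GH9"] == 2

    def test_different_families_never_merge(self):
        hits = [
            DomainHit("o1", "PF00759", 1e-10, 80.0, 10, 200),  # GH9
            DomainHit("o1", "PF00942", 1e-10, 80.0, 10, 200),  # CBM3, same span
        ]
        _, counts = screen_domain_hits(hits, load_cazy_map(), merge_overlaps=True)
        assert counts == {"GH9": 1, "CBM3": 1}


class TestRollup:
    def test_category_totals(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("PF_A\tGH5\tGH\tcellulase\nPF_B\tGH9\tGH\tcellulase\n")
        cmap = load_cazy_map(p)
        cats, gh, cbm = rollup_categories({"GH5": 2, "GH9": 3}, cmap)
        assert cats == {"cellulase": 5}
        assert gh == {"GH5": 0.4, "GH9": 0.6} and cbm == {}

    def test_gh_proportions_sum_to_one(self):
        cmap = load_cazy_map()
        counts = {"GH9": 7, "GH2": 3, "GH3": 10, "CBM3": 4, "CBM6": 1}
        cats, gh, cbm = rollup_categories(counts, cmap)
        assert sum(gh.values()) == pytest.approx(1.0)
        assert sum(cbm.values()) == pytest.approx(1.0)
        assert cats["binding"] == 5

    def test_unmapped_family_errors(self):
        with pytest.raises(InputError, match="not present"):
            rollup_categories({"GH999": 1}, load_cazy_map())

    def test_synthetic_weights_recovered(self, tiny_community):
        """Family proportions track the generating weights within binomial noise."""
        from rmorf.simulate import simulate_domain_hits

        cmap = load_cazy_map()
        weights = {"GH9": 0.5, "CBM3": 0.3, "GH2": 0.2}
        hits, truth = simulate_domain_hits(
            tiny_community.orfs * 40, cmap, p_cazy=0.8,
            family_weights=weights, decoy_fraction=0.0, seed=3,
        )
        _, counts = screen_domain_hits(hits, cmap)
        total = sum(counts.values())
        for fam, w in weights.items():
            se = np.sqrt(w * (1 - w) / total)
            assert abs(counts[fam] / total - w) < 4 * se + 0.01


class TestIdentityHistogram:
    def test_basic_binning(self):
        hist = identity_histogram({"a": 45.0, "b": 55.0})
        assert hist[(40, 50)] == 1 and hist[(50, 60)] == 1
        assert sum(hist.values()) == 2

    def test_identity_100_falls_in_closed_top_bin(self):
        hist = identity_histogram({"a": 100.0})
        assert hist[(90, 100)] == 1

    def test_out_of_range_errors(self):
        with pytest.raises(InputError, match="outside"):
            identity_histogram({"a": 101.0})

    def test_fraction_below_50_matches_enumeration(self):
        rng = np.random.default_rng(5)
        idents = {f"o{i}": float(rng.uniform(0, 100)) for i in range(500)}
        hist = identity_histogram(idents)
        below = sum(c for (lo, _hi), c in hist.items() if lo < 50)
        assert below == sum(1 for v in idents.values() if v < 50)

    def test_best_identity_uses_top_bit_score(self):
        hits = [
            ProteinHit("o1", "s1", bit_score=100.0, evalue=1e-20, identity_pct=80.0,
                       subject_taxon="t"),
            ProteinHit("o1", "s2", bit_score=200.0, evalue=1e-30, identity_pct=30.0,
                       subject_taxon="t"),
        ]
        assert best_identity_per_orf(hits) == {"o1": 30.0}
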