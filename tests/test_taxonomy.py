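"""LCA assignment: hit filtering, LCA computation, chimera rule, min-support."""

import numpy as np
import pytest

from conftest import random_tree
from rmorf.errors import InputError
from rmorf.io_formats import ProteinHit
from rmorf.taxonomy import (
    UNASSIGNED,
    LcaParams,
    apply_min_support,
    assign_orf_taxonomy,
    lca_of_taxa,
    retain_hits,
)


def _hit(orf="o1", taxon="Clostridium", score=100.0, evalue=1e-20):
    return ProteinHit(orf_id=orf, subject_id=f"s|{taxon}", bit_score=score,
                      evalue=evalue, identity_pct=50.0, subject_taxon=taxon)


class TestRetainHits:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([100.0, 85.0], [100.0]),          # 85 < 90% of best
            ([30.0], []),                       # below the 35 floor
            ([100.0, 95.0, 91.0], [100.0, 95.0, 91.0]),  # all within 10%
        ],
    )
    def test_score_floor_and_top_percent(self, scores, expected):
        hits = [_hit(score=s) for s in scores]
        kept = retain_hits(hits, LcaParams(min_score=35, top_percent=10))
        assert [h.bit_score for h in kept] == expected

    def test_empty_in_empty_out(self):
        assert retain_hits([], LcaParams()) == []


class TestLca:
    def test_singleton_is_identity(self, small_tree):
        assert lca_of_taxa({"Clostridium"}, small_tree) == "Clostridium"

    def test_cross_phylum_collapses_to_superkingdom(self, small_tree):
        taxa = {"Clostridium", "Anaerolinea"}
        assert lca_of_taxa(taxa, small_tree) == "Bacteria"

    def test_cross_superkingdom_collapses_to_root(self, small_tree):
        assert lca_of_taxa({"Clostridium", "Methanothermobacter"}, small_tree) == "root"

    def test_empty_set_is_unassigned(self, small_tree):
        assert lca_of_taxa(set(), small_tree) == UNASSIGNED

    def test_unknown_taxon_is_hard_error(self, small_tree):
        with pytest.raises(InputError, match="unknown taxon"):
            lca_of_taxa({"Klingon"}, small_tree)

    def test_monotone_adding_taxa_never_deepens(self, small_tree):
        base = lca_of_taxa({"Clostridium"}, small_tree)
        wider = lca_of_taxa({"Clostridium", "Anaerolinea"}, small_tree)
        assert small_tree.depth(wider) <= small_tree.depth(base)

    def test_matches_path_intersection_oracle_on_random_trees(self):
        """1,000 random (tree, subset) instances against explicit path intersection."""
        rng = np.random.default_rng(2024)
        n_instances = 0
        while n_instances < 1000:
            tree = random_tree(rng, n_nodes=int(rng.integers(20, 200)))
            nodes = list(tree.nodes)
            for _ in range(20):
                size = int(rng.integers(1, 8))
                subset = {nodes[i] for i in rng.integers(0, len(nodes), size=size)}
                # oracle: intersect explicit root paths, take the deepest common node
                common = set(tree.path_to_root(next(iter(subset))))
                for t in subset:
                    common &= set(tree.path_to_root(t))
                expected = max(common, key=tree.depth)
                assert lca_of_taxa(subset, tree) == expected
                n_instances += 1


class TestAssign:
    def test_uniform_hits_give_genus(self, small_tree):
        hits = [_hit(score=s) for s in (100, 98, 96)]
        assignments, counts = assign_orf_taxonomy(hits, small_tree, LcaParams(min_support=1))
        assert assignments == {"o1": "Clostridium"}
        assert counts["Clostridium"] == 1

    def test_cross_superkingdom_orf_discarded_as_chimeric(self, small_tree):
        hits = [_hit(taxon="Clostridium", score=100), _hit(taxon="Methanothermobacter", score=100)]
        assignments, _ = assign_orf_taxonomy(hits, small_tree, LcaParams(min_support=1))
        assert assignments["o1"] == UNASSIGNED  # LCA is the absolute root

    def test_cross_phylum_orf_stands_at_superkingdom(self, small_tree):
        hits = [_hit(taxon="Clostridium", score=100), _hit(taxon="Anaerolinea", score=100)]
        assignments, _ = assign_orf_taxonomy(hits, small_tree, LcaParams(min_support=1))
        assert assignments["o1"] == "Bacteria"

    def test_stricter_discard_rank(self, small_tree):
        hits = [_hit(taxon="Clostridium", score=100), _hit(taxon="Anaerolinea", score=100)]
        params = LcaParams(min_support=1, discard_rank="superkingdom")
        assignments, _ = assign_orf_taxonomy(hits, small_tree, params)
        assert assignments["o1"] == UNASSIGNED

    def test_top_percent_shields_lca_from_weak_offtarget_hit(self, small_tree):
        hits = [_hit(taxon="Clostridium", score=100), _hit(taxon="Anaerolinea", score=80)]
        assignments, _ = assign_orf_taxonomy(hits, small_tree, LcaParams(min_support=1))
        assert assignments["o1"] == "Clostridium"

    def test_order_independence(self, small_tree):
        rng = np.random.default_rng(7)
        hits = []
        for i in range(30):
            taxon = ("Clostridium", "Anaerolinea", "Methanothermobacter")[i % 3]
            hits.append(_hit(orf=f"o{i % 10}", taxon=taxon, score=float(rng.uniform(40, 200))))
        ref, _ = assign_orf_taxonomy(hits, small_tree, LcaParams(min_support=1))
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            got, _ = assign_orf_taxonomy(perm, small_tree, LcaParams(min_support=1))
            assert got == ref

    def test_unknown_subject_taxon_is_hard_error(self, small_tree):
        with pytest.raises(InputError, match="not in tree"):
            assign_orf_taxonomy([_hit(taxon="Borg")], small_tree)


class TestMinSupport:
    def test_promotion_to_supported_ancestor(self, small_tree):
        # 1 ORF at genus, 6 at the class above it: genus fails support 5,
        # its ORF is reported at the class
        assignments = {"lone": "Clostridium"}
        assignments.update({f"o{i}": "Clostridia" for i in range(6)})
        out = apply_min_support(assignments, small_tree, min_support=5)
        assert out["lone"] == "Clostridia"
        assert all(out[f"o{i}"] == "Clostridia" for i in range(6))

    def test_min_support_one_is_identity(self, small_tree):
        assignments = {"a": "Clostridium", "b": "Anaerolinea"}
        assert apply_min_support(assignments, small_tree, 1) == assignments

    def test_chain_failing_everywhere_becomes_unassigned(self, small_tree):
        assignments = {"a": "Clostridium"}
        out = apply_min_support(assignments, small_tree, min_support=5)
        assert out["a"] == UNASSIGNED

    def test_siblings_pool_support_at_parent(self, small_tree):
        # two genera with 3 ORFs each under different phyla fail alone;
        # at superkingdom 'Bacteria' they pool to 6 >= 5
        assignments = {f"c{i}": "Clostridium" for i in range(3)}
        assignments.update({f"a{i}": "Anaerolinea" for i in range(3)})
        out = apply_min_support(assignments, small_tree, min_support=5)
        assert set(out.values()) == {"Bacteria"}

    def test_drop_mode_unassigns(self, small_tree):
        out = apply_min_support({"a": "Clostridium"}, small_tree, 5, mode="drop")
        assert out["a"] == UNASSIGNED
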