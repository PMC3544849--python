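import numpy as np
import pytest

from rmorf.simulate import CommunitySpec, GenomeSpec, build_community
from rmorf.taxonomy import TaxonomyTree


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """Two bacterial phyla plus an archaeal one, down to genus."""
    rows = [
        ("root", "", "root", "root"),
        ("Bacteria", "root", "superkingdom", "Bacteria"),
        ("Archaea", "root", "superkingdom", "Archaea"),
        ("Firmicutes", "Bacteria", "phylum", "Firmicutes"),
        ("Chloroflexi", "Bacteria", "phylum", "Chloroflexi"),
        ("Euryarchaeota", "Archaea", "phylum", "Euryarchaeota"),
        ("Clostridia", "Firmicutes", "class", "Clostridia"),
        ("Clostridium", "Clostridia", "genus", "Clostridium"),
        ("Anaerolineae", "Chloroflexi", "class", "Anaerolineae"),
        ("Anaerolinea", "Anaerolineae", "genus", "Anaerolinea"),
        ("Methanobacteria", "Euryarchaeota", "class", "Methanobacteria"),
        ("Methanothermobacter", "Methanobacteria", "genus", "Methanothermobacter"),
    ]
    return TaxonomyTree.from_rows(rows)


@pytest.fixture(scope="session")
def tiny_community():
    """One small genome, a handful of ORFs — fast fixture for IO/mapping tests."""
    spec = CommunitySpec(
        genomes=(
            GenomeSpec("gA", ("root", "Bacteria", "Firmicutes"), 12_000, 10.0, 0.5),
            GenomeSpec("gB", ("root", "Bacteria", "Chloroflexi"), 12_000, 5.0, 0.5),
        ),
        seed=42,
        orf_length_range=(300, 1200),
    )
    return build_community(spec)


def random_tree(rng: np.random.Generator, n_nodes: int = 200) -> TaxonomyTree:
    """Random rank-free tree (ranks all 'clade' below the root) for LCA oracles."""
    rows = [("n0", "", "root", "n0")]
    for i in range(1, n_nodes):
        parent = f"n{int(rng.integers(0, i))}"
        rows.append((f"n{i}", parent, "clade", f"n{i}"))
    return TaxonomyTree.from_rows(rows)
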