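import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mitosel import (
    GeneAlignment,
    SequenceRecord,
    SimulationConfig,
    Tree,
    get_code,
    simulate_codon_evolution,
    simulate_tree,
)


@pytest.fixture(scope="session")
def code5():
    return get_code(5)


@pytest.fixture
def quartet_tree():
    return Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def neutral_sim(code5):
    """Small neutral simulation shared by several tests."""
    cfg = SimulationConfig(seed=11, n_tips=6, n_codons=150, depth=0.3,
                           omega_foreground=1.0, omega_background=1.0)
    tree = simulate_tree(cfg)
    aln, truth = simulate_codon_evolution(tree, cfg)
    return tree, aln, truth


@pytest.fixture(scope="session")
def contrast_sim():
    """Foreground-elevated simulation (omega 0.6 vs 0.2)."""
    cfg = SimulationConfig(seed=23, n_tips=12, n_codons=250, depth=0.3,
                           omega_foreground=0.6, omega_background=0.2,
                           foreground_fraction=0.4)
    tree = simulate_tree(cfg)
    aln, truth = simulate_codon_evolution(tree, cfg)
    return tree, aln, truth


def make_alignment(gene: str, rows: dict[str, str]) -> GeneAlignment:
    return GeneAlignment(gene, [SequenceRecord(k, v) for k, v in rows.items()])


@pytest.fixture
def toy_alignment():
    return make_alignment(
        "ATP6",
        {
            "s1": "ATTATGGCA",
            "s2": "ATCATGGCA",
            "s3": "ATTATGGCT",
            "s4": "ATTATAGCA",
        },
    )
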