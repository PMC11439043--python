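import numpy as np
import pytest

from mitosel import GeneticCode, Phylogeny
from mitosel.simulate import SimulationConfig, simulate_alignment

# 6-taxon tree with the (A,B) stem marked as foreground; branch lengths in
# expected substitutions per codon site under the background mixture.
TREE6 = "((A:0.2,B:0.3)ab#1:0.15,((C:0.25,D:0.1):0.1,(E:0.2,F:0.15):0.1):0.2);"


@pytest.fixture(scope="session")
def code5() -> GeneticCode:
    return GeneticCode.from_table_id(5)


@pytest.fixture()
def tree6() -> Phylogeny:
    return Phylogeny.from_newick(TREE6)


@pytest.fixture(scope="session")
def sim_null_300():
    """One 6-taxon, 300-codon alignment simulated under the null (omega2=1)."""
    cfg = SimulationConfig(newick=TREE6, n_sites=300, seed=20240, omega2=1.0)
    aln, labels = simulate_alignment(cfg)
    return aln, labels, Phylogeny.from_newick(TREE6)
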