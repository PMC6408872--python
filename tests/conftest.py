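import numpy as np
import pytest

from amatox import msdin_miner as mm
from amatox import synthdata as sd
from amatox.phylo import GTRGammaParams


@pytest.fixture(scope="session")
def mdan_profile():
    """Leader profile trained on MDAN-style synthetic precursors."""
    train = []
    for s in range(8):
        _, truth = sd.plant_msdin_contig(
            400, 0.49, "IWGIGCNP", "MDAN", 0, seed=90_000 + s)
        train.append(truth["precursor"])
    return mm.build_leader_profile(train, leader_len=9)


@pytest.fixture(scope="session")
def gtr_params():
    return GTRGammaParams(
        rates=np.array([1.5, 3.0, 0.9, 1.2, 3.5, 1.0]),
        freqs=np.array([0.28, 0.22, 0.24, 0.26]),
        alpha=0.8,
    )


@pytest.fixture(scope="session")
def resolvable_8taxon_tree():
    """Fixed 8-taxon tree with internal branches long enough to resolve."""
    from amatox.seqio import parse_newick
    return parse_newick(
        "(((a:0.12,b:0.15):0.1,(c:0.1,d:0.2):0.08):0.1,"
        "((e:0.15,f:0.1):0.12,(g:0.2,h:0.1):0.1):0.05);")
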