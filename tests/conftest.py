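import logging

import numpy as np
import pytest

from mitocomp.genome_io import AlignmentBlock, Taxonomy
from mitocomp.synthetic_data import (GenePlan, SimulationConfig,
                                     paper_like_config, simulate_set)

logging.disable(logging.WARNING)


def random_block(rng, gene="test", n_samples=4, n_sites=60, gap_frac=0.0,
                 is_coding=False):
    alphabet = np.array(list("ACGT"))
    m = alphabet[rng.integers(0, 4, size=(n_samples, n_sites))]
    if gap_frac:
        mask = rng.random((n_samples, n_sites)) < gap_frac
        m[mask] = "-"
    return AlignmentBlock(gene=gene,
                          samples=[f"s{i}" for i in range(n_samples)],
                          matrix=m, is_coding=is_coding)


@pytest.fixture(scope="session")
def study_sim():
    """One simulation of the frozen study-like configuration."""
    cfg = paper_like_config(seed=20210)
    return simulate_set(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A trimmed, fast simulated set: 6 tips, 4 genes."""
    tax = {}
    for sf, tr, g, sp, ind in [
            ("SF1", "TR1", "G1", "G1_sp1", "a1"),
            ("SF1", "TR1", "G1", "G1_sp1", "a2"),
            ("SF1", "TR1", "G1", "G1_sp2", "b1"),
            ("SF1", "TR1", "G2", "G2_sp1", "c1"),
            ("SF1", "TR2", "G3", "G3_sp1", "d1"),
            ("SF2", "TR3", "G4", "G4_sp1", "e1")]:
        tax[ind] = Taxonomy(sf, tr, g, sp, ind)
    tree = ("(((((a1:0.001,a2:0.001):0.029,b1:0.03):0.02,c1:0.05):0.01,"
            "d1:0.06):0.025,e1:0.085);")
    cfg = SimulationConfig(
        tree=tree, seed=7,
        gene_plan=[GenePlan("cox1", "PCG", 402, 0.8),
                   GenePlan("nad6", "PCG", 300, 1.9),
                   GenePlan("rrnS", "rRNA", 350,
                            0.5, base_freqs=(0.43, 0.066, 0.085, 0.419)),
                   GenePlan("trnA", "tRNA", 66, 0.3)],
        taxonomy=tax)
    return simulate_set(cfg)
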