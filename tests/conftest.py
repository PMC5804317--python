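import numpy as np
import pytest

import phylorates as pr


@pytest.fixture
def tiny_nuc_alignment(tmp_path):
    p = tmp_path / "tiny.fasta"
    p.write_text(">a\nACGT\n>b\nAC-T\n")
    return pr.read_alignment(p, "nucleotide")


@pytest.fixture
def two_tip_tree():
    return pr.read_tree("(a:0.1,b:0.2);")


@pytest.fixture
def jc_nuc():
    return pr.build_model("JC69-nuc")


@pytest.fixture
def wag():
    return pr.build_model("WAG")


@pytest.fixture
def small_sim():
    """10-taxon WAG simulation with known gamma-drawn site rates."""
    tree = pr.random_tree(10, seed=101)
    model = pr.build_model("WAG")
    rd = pr.discrete_gamma(0.4, 20)
    rates = pr.draw_site_rates(rd, 40, seed=102)
    aln = pr.evolve_alignment(tree, model, rates, seed=103)
    return tree, model, rates, aln


def random_state_sets(rng, taxa, n_states, gap_prob=0.15):
    """Random per-taxon allowed-state sets: mostly singletons, some gaps."""
    sets = {}
    for t in taxa:
        if rng.random() < gap_prob:
            sets[t] = tuple(range(n_states))
        else:
            sets[t] = (int(rng.integers(n_states)),)
    return sets


def pattern_from_sets(taxa, sets, n_states):
    part = np.zeros((len(taxa), n_states))
    for i, t in enumerate(taxa):
        part[i, list(sets[t])] = 1.0
    return pr.SitePattern(list(taxa), part)
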