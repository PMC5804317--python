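import math

import numpy as np
import pytest

import phylorates as pr
from phylorates.exceptions import DomainError
from phylorates.likelihood import (
    CachedPruner,
    PruningEngine,
    SitePattern,
    TreeIndex,
    compress_patterns,
    encode_columns,
)

from conftest import pattern_from_sets, random_state_sets
from oracles import brute_force_loglik, jc69_p_same


def test_two_tip_jc69_closed_form(two_tip_tree, jc_nuc):
    pat = SitePattern.from_characters(["a", "b"], "AA", "nucleotide")
    ll = pr.site_log_likelihood(two_tip_tree, jc_nuc, pat, r=1.0)
    assert ll == pytest.approx(math.log(0.25 * jc69_p_same(0.3)), abs=1e-12)


def test_all_gap_column_has_probability_one(two_tip_tree, wag, jc_nuc):
    for model, alpha in ((jc_nuc, "nucleotide"), (wag, "protein")):
        pat = SitePattern.from_characters(["a", "b"], "--", alpha)
        assert pat.is_uninformative
        assert pr.site_log_likelihood(two_tip_tree, model, pat) == pytest.approx(
            0.0, abs=1e-12
        )


def test_negative_rate_rejected(two_tip_tree, jc_nuc):
    pat = SitePattern.from_characters(["a", "b"], "AC", "nucleotide")
    with pytest.raises(DomainError):
        pr.site_log_likelihood(two_tip_tree, jc_nuc, pat, r=-0.5)


def test_rate_zero_uses_identity_transitions(two_tip_tree, jc_nuc):
    same = SitePattern.from_characters(["a", "b"], "AA", "nucleotide")
    diff = SitePattern.from_characters(["a", "b"], "AC", "nucleotide")
    assert pr.site_log_likelihood(two_tip_tree, jc_nuc, same, r=0.0) == pytest.approx(
        math.log(0.25), abs=1e-12
    )
    assert pr.site_log_likelihood(two_tip_tree, jc_nuc, diff, r=0.0) == -np.inf


@pytest.mark.parametrize("newick,n_tips", [
    ("((a:0.11,b:0.23):0.05,(c:0.4,d:0.02):0.31);", 4),
    ("(a:0.2,b:0.1,c:0.3);", 3),
    ("(((a:0.1,b:0.2):0.1,c:0.3):0.2,(d:0.15,e:0.25):0.05);", 5),
    ("((a:0.1,b:0.2,c:0.05):0.1,(d:0.3,e:0.02):0.2);", 5),  # polytomy
])
def test_pruning_equals_brute_force_enumeration(newick, n_tips):
    """Pruning matches exhaustive summation over internal states on small trees."""
    rng = np.random.default_rng(42)
    tree = pr.read_tree(newick)
    taxa = sorted(tree.tip_labels)
    for model_name in ("JC69-nuc", "HKY85", "WAG"):
        model = pr.build_model(model_name)
        for _ in range(3):
            sets = random_state_sets(rng, taxa, model.n_states)
            pat = pattern_from_sets(taxa, sets, model.n_states)
            r = float(rng.uniform(0.2, 3.0))
            mine = pr.site_log_likelihood(tree, model, pat, r=r)
            ref = brute_force_loglik(tree, model, sets, r=r)
            assert mine == pytest.approx(ref, abs=1e-10)


def test_pulley_principle_rerooting_invariance(small_sim):
    """Reversible-model likelihoods are invariant to root placement."""
    tree, model, rates, aln = small_sim
    taxa = list(aln.taxa)
    cols = aln.data[:, :10]
    base = [
        pr.site_log_likelihood(
            tree, model, SitePattern.from_characters(taxa, cols[:, j], "protein")
        )
        for j in range(cols.shape[1])
    ]
    for edge_i in (2, 7):
        rerooted = tree.clone()
        edges = [e for e in rerooted.dtree.preorder_edge_iter() if e.length]
        rerooted.dtree.reroot_at_edge(
            edges[edge_i], length1=edges[edge_i].length / 2,
            length2=edges[edge_i].length / 2, update_bipartitions=False,
        )
        for j, ref in enumerate(base):
            ll = pr.site_log_likelihood(
                rerooted, model,
                SitePattern.from_characters(taxa, cols[:, j], "protein"),
            )
            assert ll == pytest.approx(ref, abs=1e-9)


def test_scaling_identity_lengths_times_rate(small_sim):
    """L(b*c, r) = L(b, r*c): only the product of lengths and rate matters."""
    tree, model, rates, aln = small_sim
    taxa = list(aln.taxa)
    pat = SitePattern.from_characters(taxa, aln.column(0), "protein")
    rng = np.random.default_rng(5)
    for _ in range(5):
        c = float(rng.uniform(0.1, 5.0))
        r = float(rng.uniform(0.1, 5.0))
        scaled = tree.clone()
        for nd in scaled.dtree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= c
        assert pr.site_log_likelihood(scaled, model, pat, r) == pytest.approx(
            pr.site_log_likelihood(tree, model, pat, r * c), abs=1e-9
        )


class TestPartitionLikelihood:
    def test_sum_of_per_site_values(self, small_sim):
        tree, model, rates, aln = small_sim
        taxa = list(aln.taxa)
        total = pr.partition_log_likelihood(tree, model, aln.data, taxa, "protein")
        per_site = sum(
            pr.site_log_likelihood(
                tree, model, SitePattern.from_characters(taxa, aln.column(j), "protein")
            )
            for j in range(aln.length)
        )
        assert total == pytest.approx(per_site, rel=1e-12)

    def test_duplicated_column_counts_twice(self, two_tip_tree, jc_nuc):
        cols = np.array([["A", "A", "C"], ["A", "A", "G"]])
        total = pr.partition_log_likelihood(
            two_tip_tree, jc_nuc, cols, ["a", "b"], "nucleotide"
        )
        single = pr.partition_log_likelihood(
            two_tip_tree, jc_nuc, cols[:, [0, 2]], ["a", "b"], "nucleotide"
        )
        extra = pr.partition_log_likelihood(
            two_tip_tree, jc_nuc, cols[:, [0]], ["a", "b"], "nucleotide"
        )
        assert total == pytest.approx(single + extra, rel=1e-12)

    def test_one_category_mixture_equals_no_mixture(self, small_sim):
        tree, model, rates, aln = small_sim
        taxa = list(aln.taxa)
        rd = pr.RateDistribution(np.array([1.0]), np.array([1.0]), "gamma")
        a = pr.partition_log_likelihood(tree, model, aln.data, taxa, "protein")
        b = pr.partition_log_likelihood(
            tree, model, aln.data, taxa, "protein", rate_dist=rd
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_gamma_mixture_mixes_categories(self, two_tip_tree, jc_nuc):
        cols = np.array([["A"], ["C"]])
        rd = pr.discrete_gamma(0.5, 4)
        got = pr.partition_log_likelihood(
            two_tip_tree, jc_nuc, cols, ["a", "b"], "nucleotide", rate_dist=rd
        )
        by_hand = math.log(sum(
            w * math.exp(pr.partition_log_likelihood(
                two_tip_tree, jc_nuc, cols, ["a", "b"], "nucleotide",
                lengths=None, site_rates=np.array([r]),
            ))
            for r, w in zip(rd.rates, rd.weights)
        ))
        assert got == pytest.approx(by_hand, abs=1e-10)


def test_no_underflow_on_two_thousand_tips():
    """Site log-likelihoods stay finite on a 2,000-tip simulated tree."""
    tree = pr.random_tree(2000, seed=9)
    model = pr.build_model("JC69-nuc")
    rates = np.ones(20)
    aln = pr.evolve_alignment(tree, model, rates, seed=10)
    index = TreeIndex(tree, aln.taxa)
    pats, counts, _ = compress_patterns(aln.data)
    eng = PruningEngine(index, model, encode_columns(pats, aln.taxa, "nucleotide"))
    lls = eng.site_log_likelihoods()
    assert np.all(np.isfinite(lls))
    # the raw product would underflow: check scaling actually engaged
    assert lls.min() < -700


def test_cached_pruner_matches_fresh_evaluation(small_sim):
    tree, model, rates, aln = small_sim
    index = TreeIndex(tree, aln.taxa)
    pats, counts, _ = compress_patterns(aln.data)
    eng = PruningEngine(index, model, encode_columns(pats, aln.taxa, "protein"))
    cached = CachedPruner(eng)
    assert np.abs(cached.site_logliks() - eng.site_log_likelihoods()).max() < 1e-10
    # trial evaluation then commit agree with a fresh full pruning
    v = index.nonroot_nodes()[3]
    trial = cached.branch_site_logliks(v, 0.77)
    cached.commit_branch(v, 0.77)
    assert np.abs(trial - cached.site_logliks()).max() < 1e-10
    fresh = eng.site_log_likelihoods()
    assert np.abs(trial - fresh).max() < 1e-10
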