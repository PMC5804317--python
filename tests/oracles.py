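"""Independent reference computations used to check the implementation.

These deliberately avoid the package's pruning/eigendecomposition code:
transition matrices come from scipy's generic matrix exponential and
likelihoods from explicit enumeration over internal-node states.
"""

import itertools

import numpy as np
from scipy.linalg import expm


def jc69_p_same(t):
    """JC69 probability of observing the same nucleotide after time t."""
    return 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)


def jc69_p_diff(t):
    return 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)


def jc69_distance(p_hat):
    """JC69 ML distance from an observed proportion of differing sites."""
    return -0.75 * np.log(1.0 - 4.0 * p_hat / 3.0)


def brute_force_loglik(tree, model, state_sets, r=1.0):
    """Site log-likelihood by summation over all internal-node states.

    ``tree`` is a phylorates Tree; ``state_sets`` maps taxon label to an
    iterable of allowed state indices.  P(t) is computed with scipy.expm,
    independently of the package's eigendecomposition.  Exponential in the
    number of internal nodes: only use on tiny trees.
    """
    dtree = tree.dtree
    root = dtree.seed_node
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    tips = list(dtree.leaf_node_iter())
    n = model.n_states
    pmat = {}
    for nd in dtree.preorder_node_iter():
        if nd is not root:
            pmat[nd] = expm(model.Q * (nd.edge.length * r))
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = model.pi[amap[root]]
        for nd in internals:
            if nd is not root:
                prob *= pmat[nd][amap[nd.parent_node], amap[nd]]
        for tip in tips:
            allowed = state_sets[tip.taxon.label]
            prob *= sum(pmat[tip][amap[tip.parent_node], s] for s in allowed)
        total += prob
    return float(np.log(total))


def discrete_gamma_rates_by_quadrature(alpha, k):
    """Mean-of-bin discrete gamma rates via direct numerical integration."""
    from scipy import integrate
    from scipy.stats import gamma

    edges = np.concatenate(
        [[0.0], gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha), [np.inf]]
    )
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(
            lambda x: x * gamma.pdf(x, a=alpha, scale=1.0 / alpha),
            lo, min(hi, 1e3), limit=200,
        )
        rates.append(k * val)
    return np.array(rates)
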