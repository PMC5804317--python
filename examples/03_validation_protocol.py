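"""Accuracy of rate recovery as a function of taxon count.

Simulates one replicate of the validation protocol (25/50/100-taxon trees
with mean branch length 0.27; 100-site WAG alignments; site rates from a
20-category discrete gamma with shape 0.4, shared across taxon counts) and
reports how well inferred rates correlate with the generating truth.
"""

import numpy as np

import phylorates as pr
from phylorates.io import bind_partitions
from phylorates.likelihood import SitePattern
from phylorates.optimize import build_model_for, fit_partition

bundles = pr.paper_protocol(replicates=1, seed=2024)

for b in bundles:
    pset = bind_partitions(b.alignment, b.tree)
    model = build_model_for("WAG", b.alignment)
    fit = fit_partition(b.alignment, pset.partitions[0], model)
    solver = pr.SiteRateSolver.from_fit(fit)
    ests = [
        solver.estimate(SitePattern.from_characters(
            list(b.alignment.taxa), b.alignment.column(j), "protein"))
        for j in range(b.alignment.length)
    ]
    interior = np.array([not e.at_upper_bound for e in ests])
    r = np.array([e.r_mle for e in ests])
    r2 = np.corrcoef(r[interior], b.true_rates[interior])[0, 1] ** 2
    print(f"{b.n_taxa:>3} taxa: R^2(inferred, true) = {r2:.3f} "
          f"over {interior.sum()} sites "
          f"({(~interior).sum()} saturated site(s) flagged at the bound)")

print("\nMore taxa give more substitutions per site and therefore sharper")
print("per-site rate estimates: R^2 should increase down the list.")
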