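# phylorates

Relative site-wise evolutionary rate inference for nucleotide and protein
alignments on a fixed phylogeny.

Comparative biologists routinely ask *which positions of a gene are
conserved and which evolve quickly* — to find functional residues, score
constraint, or feed downstream evolutionary analyses. `phylorates`
answers this with a two-stage maximum-likelihood procedure:

1. **Branch lengths.** Given an alignment and a tree topology, fit
   alignment-wide branch lengths (in expected substitutions per site)
   under a reversible substitution model `q_ij = S_ij π_j`, normalized so
   the mean substitution rate at equilibrium is 1.
2. **Per-site rates.** At each site *s*, estimate a single scaler *r_s ≥
   0* that multiplies every fitted branch length, by maximizing that
   site's likelihood. *r_s* is the site's evolutionary rate relative to
   the alignment-wide mean: 2 means twice as fast as an average site, 0.5
   half as fast.

Each estimate carries an approximate 95% confidence interval from the
profile likelihood (all *r* within χ²₁(0.95)/2 ≈ 1.92 log-units of the
maximum). The likelihood engine is underflow-safe (tested on 2,000-tip
trees), reports a rate for **every** column — including all-gap ones,
which are flagged as uninformative rather than skipped — and supports
site-partitioned alignments with a separate phylogeny per partition (for
data with recombination breakpoints). Models: GTR, HKY85, JC69
(nucleotide); WAG, LG, JTT, JC69 (protein); any PAML-format empirical
matrix via `custom:<file>`. Optional discrete-gamma or general-discrete
rate variation is available for the branch-length stage, but the
recommended default is off: site-to-site heterogeneity belongs in the
per-site scalers, not split between two parameter sets.

## Worked example

```python
import phylorates as pr

# a small simulated data set with known per-site rates
tree = pr.random_tree(15, mean_branch_length=0.27, seed=42)
true_rates = pr.draw_site_rates(pr.discrete_gamma(0.4, 20), 30, seed=43)
aln = pr.evolve_alignment(tree, pr.build_model("WAG"), true_rates, seed=44)

doc = pr.run_analysis(aln, tree, "WAG", progress=False)
for site, (part, mle, lo, hi, logl) in enumerate(doc.content[:3], start=1):
    print(f"site {site}: r = {mle:.3f}  95% CI [{lo:.3f}, {hi:.3f}]")
```

prints (run `python examples/01_infer_site_rates.py` for the full table):

```
site 1: r = 1.723  95% CI [0.705, 3.731]
site 2: r = 0.000  95% CI [0.000, 0.343]
site 3: r = 0.000  95% CI [0.000, 1.011]
```

Site 1 evolves about 1.7× faster than the average site; sites 2 and 3 are
invariant in this sample — their MLE is 0 (flagged as a boundary
estimate) and the interval upper bound says how fast they could plausibly
be evolving given that nothing changed. In that example 29 of 30 true generating rates
fall inside their 95% interval. Each row of `doc.content` is
`[partition, MLE, lower, upper, logL]`; `pr.write_results(doc, path)`
writes the document as JSON next to the input with the suffix
`.leisr.json`.

The same analysis from a shell:

```bash
phylorates infer --alignment data.fasta --tree tree.nwk \
    --type protein --model WAG
phylorates simulate --seed 7 --out sims/   # validation data with truth
```

The `examples/` directory holds short narrative scripts: single-gene
inference against known truth, a partitioned analysis, and the
taxon-count accuracy sweep.

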