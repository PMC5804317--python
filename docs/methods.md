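# Methods

## The model and the two-stage procedure

`phylorates` infers a *relative evolutionary rate* for every site of a
nucleotide or protein alignment, given a fixed tree topology. The
substitution process is a reversible continuous-time Markov chain with
generator

    q_ij = S_ij * pi_j   (i != j),

where `S` is a symmetric exchangeability matrix and `pi` the equilibrium
frequencies. The generator is normalized so that the expected substitution
rate at equilibrium is one, `-sum_i pi_i q_ii = 1`; branch lengths are then
in expected substitutions per site. Transition probabilities `P(t) =
exp(Qt)` are obtained from the eigendecomposition of the symmetrized matrix
`diag(sqrt(pi)) Q diag(1/sqrt(pi))`, which is guaranteed real for
reversible models and lets one decomposition serve every branch length.

Inference proceeds in two stages:

1. **Alignment-wide branch lengths.** With the topology fixed, branch
   lengths (and any free model parameters) are fitted by maximum likelihood
   to all sites of a partition jointly. Optionally the fit can include
   among-site rate variation — a discrete gamma distribution or a general
   discrete distribution (GDD) — but the recommended default is *no* rate
   variation at this stage: site-to-site heterogeneity should be absorbed by
   the per-site scalers of stage 2, not split between two parameter sets.
2. **Per-site rate scalers.** For each site `s`, a single scaler `r_s >= 0`
   multiplies every fitted branch length, and `r_s` is chosen to maximize
   that site's likelihood. Because stage 1 already calibrates the tree to
   the alignment-wide average rate, `r_s` is interpretable as the rate of
   site `s` relative to the partition mean; `r = 2` means twice the average
   rate.

An approximate 95% confidence interval for each `r_s` comes from the
profile likelihood: the set of `r` whose log-likelihood is within
`chi2_1(0.95)/2 = 1.92073` of the maximum. Other confidence levels use the
corresponding chi-square quantile.

## Likelihood engine

Site likelihoods are computed by Felsenstein pruning over a postorder
node indexing, vectorized across unique alignment columns (identical
columns are computed once and weighted — pattern compression). Gap
characters (`-`, `?`, `.`) are fully missing data (all-ones tip partial);
IUPAC nucleotide codes and protein X/B/Z are partially missing. This is
what makes a rate estimate available at *every* column, including all-gap
ones.

Conditional likelihood vectors are renormalized per pattern whenever their
maximum drops below `1e-80`, with the log of the scaling factor
accumulated separately. The check runs after *every* child multiplication,
not once per node: two already-small child messages can otherwise multiply
to an exact floating-point zero before any once-per-node check fires. With
this scheme alignments with thousands of sequences do not underflow; the
test suite exercises a 2,000-tip tree under WAG with strong rate
heterogeneity and checks every site log-likelihood is finite.

During branch-length optimization the engine caches, for each node, the
"message" it sends to its parent (`clv @ P(t)^T` plus its subtree's
accumulated scaling log). Re-evaluating the likelihood after changing one
branch then costs only the path from that branch to the root, which is
what makes per-branch Brent iterations cheap.

Degenerate inputs handled analytically rather than as limits:

- `r = 0` (or a zero-length branch) uses an exact identity transition
  matrix; invariant columns legitimately drive `r` to 0.
- All-gap columns have likelihood exactly 1 (`log L = 0`) at every `r`;
  they are reported with `r = 1`, CI `[0, r_max]` and an `uninformative`
  flag.
- Negative eigen-reconstruction residuals in `P(t)` (order 1e-16) are
  clamped to zero.

## Optimization choices

- **Stage 1** is coordinate ascent: one bounded Brent maximization per
  branch on a log10 scale over `[1e-10, 1e4]`, followed by L-BFGS-B on the
  free model parameters (GTR exchangeabilities and HKY85 kappa in log
  space; gamma shape in log space; GDD rates and weights in log/softmax
  space, re-normalized to mean one). Moves are only committed when they
  improve the likelihood, so the trace is monotone. The outer loop stops
  when a sweep gains less than `1e-6` log-units (well below the 1.92
  log-unit resolution the CIs care about) or after 200 sweeps. Branches
  with no input length start at 0.1.
- **Stage 2** maximizes each site's log-likelihood over
  `r in [0, 1e4]` by bounded Brent on `log10(r + 1e-9)`, bracketed by the
  best of the coarse candidates `{0, 0.01, 1, 100, 1e4}`. An optimum within
  `1e-10` log-units of an interval endpoint is reported *at* the bound and
  flagged. The cap `1e4` is far above any plausible relative rate; fully
  saturated columns (so many substitutions that the likelihood rises
  monotonically to its asymptote) genuinely end up there, and the flag is
  the honest description of that situation.
- **Profile CI bounds** are located by bisection on the same log scale,
  stopping when the bracket is relatively tighter than ~1e-4 or the
  log-likelihood is within 1e-5 of the target drop; interior endpoints
  reproduce the 1.92073 drop to well under 1e-3. When even the search
  bound stays above the target drop, the CI is clamped there and flagged.
- Rate distributions are constrained to mean one (gamma by the mean-of-bin
  construction, GDD by explicit rescaling) so that branch lengths remain
  identifiable.

## Frequencies

JC69 variants always use uniform frequencies. GTR and HKY85 estimate
frequencies from alignment counts (with a pseudocount of 0.5 per state).
Empirical protein models (WAG, LG, JTT, or a user-supplied PAML-style
matrix) default to alignment counts (+F) as well — the convention that
serves skewed compositions best — but accept `freq_mode="model"` to use the
published vectors.

## The simulator and what it does (not) emulate

`simulate` exists so the whole pipeline can be validated against known
truth. `random_tree` builds a topology by sequential random joins with
i.i.d. exponential branch lengths; the controlled quantity is the mean
branch length (default 0.27), matching the validation conditions the
defaults target (trees of 25/50/100 taxa, 100-site WAG alignments, site
rates from a 20-category discrete gamma with shape 0.4, one rate draw
shared across taxon counts within a replicate). Sequences evolve by exact
Markov sampling: root states from `pi`, child states from the
`P(branch * site rate)` row of the parent state.

The simulator intentionally omits indels (gaps in real alignments arise
from alignment, not from this process), codon structure, among-branch rate
variation, and compositional heterogeneity. Passing the recovery tests
therefore demonstrates correctness of the estimator under its own model
class, not robustness to real-data misspecification.

## Validation design and problem sizes

The test suite and the acceptance script use problem sizes chosen to keep
a full run comfortable on one CPU while preserving the phenomena being
tested: pruning-vs-enumeration equivalence on trees of up to 5 tips (50
random cases), rate recovery on one replicate per seed of the 25/50/100
taxon protocol (5 seeds), CI coverage on 500 simulated sites of a
100-taxon tree, and the underflow check on a 2,000-tip tree.

Recovery is summarized by Pearson R^2 between inferred and true rates over
sites whose MLE is interior (not flagged at the search bound): a
boundary-flagged estimate carries no magnitude information, and one such
saturated site per hundred would otherwise dominate the statistic. Pearson
R^2 is invariant to rescaling, so mean- or median-normalization does not
change it. The accuracy floor asserted at 100 taxa was calibrated once
with an independent grid-search-only maximizer (a dense 513-point
logarithmic grid replacing Brent) on seeds disjoint from tuning, and the
gamma category rates are verified against direct numerical quadrature.

Coverage of the 95% profile CIs is expected in the 0.88-0.99 band rather
than exactly 0.95: the intervals are approximate (profile construction,
finite trees, boundary effects at `r = 0` for slow sites). Coverage is
evaluated on a common relative scale: inferred rates are relative to the
*fitted* alignment-wide average — which differs from the simulating tree's
scale when stage 1, by design, ignores rate variation — so estimates/CIs
and the generating rates are each divided by their median before checking
interval membership. The median, rather than the mean, is the robust
choice for a rate distribution as overdispersed and zero-inflated as a
shape-0.4 gamma, where occasional boundary-flagged saturated estimates
would dominate a mean.

## Known limitations

- Rates at saturated sites are reported as boundary-flagged rather than as
  finite numbers; downstream users should treat them as "very fast", not
  as measurements.
- The GDD fit uses a redundant parameterization (rates and weights both
  free, then renormalized); with many categories the optimum is flat and
  category identity is arbitrary, which is inherent to the distribution.
- Stage-1 coordinate ascent converges to a stationary point; for very flat
  likelihood surfaces (tiny alignments) different sweep orders could stop
  at slightly different lengths, though all tests run well inside the 1e-6
  tolerance.
- No ascertainment-bias correction and no codon models.
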