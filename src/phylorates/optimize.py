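"""Stage 1: maximum-likelihood branch lengths and model parameters.

The fit alternates (a) one bounded Brent maximization per branch length,
using cached pruning messages so each trial only recomputes the path from
the branch to the root, and (b) bounded multivariate refinement of any free
model parameters (GTR exchangeabilities, HKY85 kappa, gamma shape, GDD
rates/weights).  The topology is never altered.  Branch lengths are
searched on a log10 scale within [1e-10, 1e4].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from . import io as pio
from . import models
from .exceptions import DomainError, PhyloratesError
from .likelihood import (
    CachedPruner,
    PruningEngine,
    TreeIndex,
    compress_patterns,
    encode_columns,
)

BL_MIN = 1e-10
BL_MAX = 1e4
_XLO, _XHI = np.log10(BL_MIN), np.log10(BL_MAX)
DEFAULT_START_LENGTH = 0.1
CONVERGENCE_TOL = 1e-6
MAX_SWEEPS = 200


@dataclass
class FitResult:
    """Fitted branch lengths and parameters for one partition."""

    tree: pio.Tree                      # topology with fitted branch lengths
    model: models.SubstitutionModel
    rate_dist: models.RateDistribution
    log_likelihood: float
    lengths: np.ndarray                 # per TreeIndex node, root entry unused
    taxa: list
    alphabet: str
    n_sweeps: int
    converged: bool
    history: list = field(default_factory=list)

    @property
    def tree_length(self) -> float:
        root = len(self.lengths) - 1
        return float(self.lengths.sum() - self.lengths[root])


class _MixtureState:
    """Cached pruners, one per rate category, sharing branch lengths."""

    def __init__(self, engine: PruningEngine, rate_dist: models.RateDistribution,
                 counts: np.ndarray):
        self.engine = engine
        self.rate_dist = rate_dist
        self.counts = counts
        self.pruners = [CachedPruner(engine, rate=float(r)) for r in rate_dist.rates]

    def _combine(self, per_cat: np.ndarray) -> float:
        if len(self.pruners) == 1:
            site_ll = per_cat[0]
        else:
            site_ll = logsumexp(
                per_cat + np.log(self.rate_dist.weights)[:, None], axis=0
            )
        return float(self.counts @ site_ll)

    def total(self) -> float:
        return self._combine(np.stack([p.site_logliks() for p in self.pruners]))

    def branch_total(self, v: int, t: float) -> float:
        return self._combine(
            np.stack([p.branch_site_logliks(v, t) for p in self.pruners])
        )

    def commit(self, v: int, t: float) -> None:
        for p in self.pruners:
            p.commit_branch(v, t)

    def rebuild(self, model=None, rate_dist=None) -> None:
        if model is not None:
            self.engine.set_model(model)
        if rate_dist is not None:
            self.rate_dist = rate_dist
            self.pruners = [
                CachedPruner(self.engine, rate=float(r)) for r in rate_dist.rates
            ]
        else:
            for p in self.pruners:
                p.refresh()


def _free_loglik(engine, counts, model, rate_dist) -> float:
    """Total log-likelihood for trial (model, rate_dist) at current lengths."""
    engine.set_model(model)
    per_cat = np.stack(
        [engine.site_log_likelihoods(rate=float(r)) for r in rate_dist.rates]
    )
    if rate_dist.k == 1:
        site_ll = per_cat[0]
    else:
        site_ll = logsumexp(per_cat + np.log(rate_dist.weights)[:, None], axis=0)
    return float(counts @ site_ll)


def _initial_rate_dist(family: str, k: Optional[int]) -> models.RateDistribution:
    if family == "none":
        return models.constant_rate()
    if family == "gamma":
        k = 4 if k is None else int(k)
        return models.discrete_gamma(1.0, k)
    if family == "gdd":
        k = 3 if k is None else int(k)
        base = np.geomspace(0.5, 2.0, k) if k > 1 else np.array([1.0])
        return models.general_discrete(base, np.full(k, 1.0 / k))
    raise DomainError(f"rate_dist_family must be none/gamma/gdd, not {family!r}")


def _pack_free(model, rate_dist):
    """Vector of transformed free parameters (log scale / logits)."""
    x = []
    if model.name == "GTR":
        x.extend(np.log(model.free_params["rates"]))
    elif model.name == "HKY85":
        x.append(np.log(model.free_params["kappa"]))
    if rate_dist.family == "gamma" and rate_dist.k > 1:
        x.append(np.log(rate_dist.params["alpha"]))
    elif rate_dist.family == "gdd" and rate_dist.k > 1:
        x.extend(np.log(np.clip(rate_dist.rates, 1e-8, None)))
        x.extend(np.log(rate_dist.weights))
    return np.array(x)


def _unpack_free(x, model, rate_dist):
    i = 0
    new_model = model
    if model.name == "GTR":
        rates = np.exp(x[i:i + 5]); i += 5
        new_model = model.with_exchangeabilities(
            models.gtr_exchangeabilities(rates), rates=rates
        )
        new_model.name = "GTR"
    elif model.name == "HKY85":
        kappa = float(np.exp(x[i])); i += 1
        new_model = model.with_exchangeabilities(
            models.hky_exchangeabilities(kappa), kappa=kappa
        )
        new_model.name = "HKY85"
    new_rd = rate_dist
    if rate_dist.family == "gamma" and rate_dist.k > 1:
        alpha = float(np.exp(x[i])); i += 1
        new_rd = models.discrete_gamma(alpha, rate_dist.k)
    elif rate_dist.family == "gdd" and rate_dist.k > 1:
        k = rate_dist.k
        r = np.exp(x[i:i + k]); i += k
        w = np.exp(x[i:i + k]); i += k
        new_rd = models.general_discrete(r, w)
    return new_model, new_rd


def _has_free_params(model, rate_dist) -> bool:
    return bool(_pack_free(model, rate_dist).size)


def fit_partition(
    aln: pio.Alignment,
    partition: pio.Partition,
    model: models.SubstitutionModel,
    rate_dist_family: str = "none",
    k: Optional[int] = None,
    start_lengths: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit branch lengths (and free parameters) for one partition.

    Input-tree branch lengths, when present, are the starting point;
    otherwise every branch starts at 0.1.  Terminates when an outer sweep
    improves the log-likelihood by less than 1e-6, or after 200 sweeps.
    """
    index = TreeIndex(partition.tree, aln.taxa, default_length=DEFAULT_START_LENGTH)
    columns = aln.data[:, partition.sites]
    pats, counts, _ = compress_patterns(columns)
    engine = PruningEngine(index, model, encode_columns(pats, aln.taxa, aln.alphabet))
    if start_lengths is not None:
        engine.lengths = np.asarray(start_lengths, dtype=float).copy()
    np.clip(engine.lengths, BL_MIN, BL_MAX, out=engine.lengths)
    engine.lengths[index.root] = 0.0

    rate_dist = _initial_rate_dist(rate_dist_family, k)
    state = _MixtureState(engine, rate_dist, counts)
    current = state.total()
    if not np.isfinite(current):
        site_ll = engine.site_log_likelihoods(rate=1.0)
        bad = int(np.argmax(~np.isfinite(site_ll))) + 1
        raise PhyloratesError(
            f"non-finite log-likelihood at the start point (pattern {bad}); "
            "check the alignment and starting branch lengths"
        )
    history = [current]
    branches = [v for v in range(index.n_nodes) if v != index.root]
    converged = False
    sweeps = 0
    for sweeps in range(1, MAX_SWEEPS + 1):
        for v in branches:
            res = minimize_scalar(
                lambda x: -state.branch_total(v, 10.0 ** x),
                bounds=(_XLO, _XHI),
                method="bounded",
                options={"xatol": 1e-7},
            )
            t_new = float(10.0 ** res.x)
            if -res.fun > current:
                state.commit(v, t_new)
                current = -res.fun
        if _has_free_params(engine.model, state.rate_dist):
            x0 = _pack_free(engine.model, state.rate_dist)
            base_model, base_rd = engine.model, state.rate_dist

            def neg(x):
                m, rd = _unpack_free(x, base_model, base_rd)
                return -_free_loglik(engine, counts, m, rd)

            out = minimize(neg, x0, method="L-BFGS-B",
                           bounds=[(-12.0, 12.0)] * len(x0))
            if -out.fun > current:
                m, rd = _unpack_free(out.x, base_model, base_rd)
                state.rebuild(model=m, rate_dist=rd)
                current = -out.fun
            else:
                engine.set_model(base_model)
                state.rebuild()  # restore caches under the unchanged model
        history.append(current)
        if history[-1] - history[-2] < CONVERGENCE_TOL:
            converged = True
            break
    fitted_lengths = engine.lengths.copy()
    return FitResult(
        tree=index.tree_with_lengths(fitted_lengths),
        model=engine.model,
        rate_dist=state.rate_dist,
        log_likelihood=current,
        lengths=fitted_lengths,
        taxa=list(aln.taxa),
        alphabet=aln.alphabet,
        n_sweeps=sweeps,
        converged=converged,
        history=history,
    )


def fit_all(
    aln: pio.Alignment,
    partitions: pio.PartitionSet,
    model_name: str,
    freq_mode: str = "default",
    rate_dist_family: str = "none",
    k: Optional[int] = None,
) -> list:
    """Fit every partition independently with its own tree and frequencies."""
    results = []
    for part in partitions:
        # frequencies are estimated from the partition's own sites
        model = build_model_for(model_name, sub_full(aln, part), freq_mode)
        results.append(fit_partition(aln, part, model,
                                     rate_dist_family=rate_dist_family, k=k))
    return results


def sub_full(aln: pio.Alignment, part: pio.Partition) -> pio.Alignment:
    """Alignment restricted to a partition, re-indexed from site 1."""
    return pio.Alignment(
        taxa=list(aln.taxa), data=aln.data[:, part.sites], alphabet=aln.alphabet
    )


def build_model_for(name: str, aln: pio.Alignment, freq_mode: str = "default"):
    """Build a model with the package's default frequency conventions.

    JC69 variants are always uniform; GTR/HKY85 always use observed counts;
    empirical protein models default to observed (+F) but honour an explicit
    freq_mode.
    """
    if name.startswith("JC69"):
        return models.build_model(name)
    if name in ("GTR", "HKY85"):
        return models.build_model(name, aln, freq_mode="observed")
    mode = "observed" if freq_mode == "default" else freq_mode
    return models.build_model(name, aln, freq_mode=mode)
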