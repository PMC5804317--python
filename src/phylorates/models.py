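"""Reversible substitution models and among-site rate distributions.

A model is specified by a symmetric exchangeability matrix ``S`` and
equilibrium frequencies ``pi``; the instantaneous rate matrix has
off-diagonal entries ``q_ij = S_ij * pi_j`` and is normalized so the
expected substitution rate at equilibrium is 1, i.e. branch lengths are in
expected substitutions per site.  Transition probabilities P(t) = exp(Qt)
are computed from the eigendecomposition of the symmetrized matrix
``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is real for reversible models.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from . import io as pio
from .exceptions import DomainError, FormatError

NUCLEOTIDE_MODELS = ("GTR", "HKY85", "JC69-nuc")
PROTEIN_MODELS = ("WAG", "LG", "JTT", "JC69-prot")

# amino-acid model data files bundled with the package (PAML format)
_EMPIRICAL_FILES = {"WAG": "wag.dat", "LG": "lg.dat", "JTT": "jtt.dat"}

# HKY85 transition pairs in ACGT order: A<->G and C<->T
_HKY_TRANSITIONS = ((0, 2), (1, 3))


@dataclass
class SubstitutionModel:
    """Normalized reversible continuous-time Markov substitution model."""

    name: str
    states: str
    S: np.ndarray          # symmetric exchangeabilities, zero diagonal
    pi: np.ndarray         # equilibrium frequencies, sum 1
    Q: np.ndarray = field(init=False)
    # eigendecomposition of Q (right eigenvectors U, eigenvalues, U^-1)
    _evals: np.ndarray = field(init=False, repr=False)
    _U: np.ndarray = field(init=False, repr=False)
    _Uinv: np.ndarray = field(init=False, repr=False)
    free_params: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.states)
        if self.S.shape != (n, n) or self.pi.shape != (n,):
            raise DomainError("model matrix/frequency dimensions do not match states")
        if np.any(self.pi <= 0):
            raise DomainError("equilibrium frequencies must be strictly positive")
        self.pi = self.pi / self.pi.sum()
        if not np.allclose(self.S, self.S.T):
            raise DomainError("exchangeability matrix must be symmetric")
        Q = self.S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.pi, np.diag(Q)))
        if mu <= 0:
            raise DomainError("degenerate rate matrix (zero total rate)")
        Q /= mu
        self.S = self.S / mu
        self.Q = Q
        # symmetrized eigendecomposition: real spectrum for reversible Q
        sq = np.sqrt(self.pi)
        A = (sq[:, None] * Q) / sq[None, :]
        A = 0.5 * (A + A.T)
        evals, V = np.linalg.eigh(A)
        self._evals = evals
        self._U = V / sq[:, None]
        self._Uinv = V.T * sq[None, :]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def eig(self):
        return self._evals, self._U, self._Uinv

    def with_exchangeabilities(self, S: np.ndarray, **free) -> "SubstitutionModel":
        m = SubstitutionModel(name=self.name, states=self.states,
                              S=np.asarray(S, dtype=float), pi=self.pi.copy())
        m.free_params = dict(free)
        return m


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clamped into [0, 1]."""
    if not np.isfinite(t) or t < 0:
        raise DomainError(f"branch length * rate must be finite and >= 0, got {t}")
    evals, U, Uinv = model.eig()
    P = (U * np.exp(evals * t)[None, :]) @ Uinv
    np.clip(P, 0.0, None, out=P)
    return P


def transition_matrices(model: SubstitutionModel, ts: np.ndarray) -> np.ndarray:
    """Batched P(t) for an array of branch-length*rate values, shape (..., n, n)."""
    ts = np.asarray(ts, dtype=float)
    if np.any(~np.isfinite(ts)) or np.any(ts < 0):
        raise DomainError("branch length * rate values must be finite and >= 0")
    evals, U, Uinv = model.eig()
    E = np.exp(np.multiply.outer(ts, evals))          # (..., n)
    P = np.einsum("ij,...j,jk->...ik", U, E, Uinv)
    np.clip(P, 0.0, None, out=P)
    return P


def observed_frequencies(aln: pio.Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """State frequencies from alignment counts; gaps/ambiguities are skipped."""
    states = pio.alphabet_states(aln.alphabet)
    counts = np.full(len(states), pseudocount)
    flat = aln.data.ravel()
    for i, s in enumerate(states):
        counts[i] += int((flat == s).sum())
    return counts / counts.sum()


def parse_paml_matrix(path, n_states: int = 20):
    """Read a PAML-style empirical matrix file.

    Lower-triangular exchangeabilities (rows 2..n, whitespace separated,
    possibly wrapped over several lines) followed by one line of n
    equilibrium frequencies.
    """
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                tokens.extend(line.split())
    n_tri = n_states * (n_states - 1) // 2
    if len(tokens) < n_tri + n_states:
        raise FormatError(
            f"{path}: expected {n_tri} exchangeabilities + {n_states} "
            f"frequencies, found {len(tokens)} numbers"
        )
    try:
        vals = [float(x) for x in tokens[: n_tri + n_states]]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry in matrix file") from exc
    S = np.zeros((n_states, n_states))
    k = 0
    for i in range(1, n_states):
        for j in range(i):
            S[i, j] = S[j, i] = vals[k]
            k += 1
    pi = np.array(vals[n_tri: n_tri + n_states])
    if np.any(pi <= 0):
        raise FormatError(f"{path}: frequencies must be positive")
    return S, pi / pi.sum()


def _bundled_matrix(name: str):
    ref = importlib.resources.files("phylorates").joinpath(
        "data", _EMPIRICAL_FILES[name]
    )
    with importlib.resources.as_file(ref) as p:
        return parse_paml_matrix(p)


def build_model(
    name: str,
    aln: Optional[pio.Alignment] = None,
    freq_mode: str = "model",
) -> SubstitutionModel:
    """Construct a named substitution model.

    ``freq_mode='observed'`` estimates frequencies from alignment counts with
    a pseudocount of 0.5 per state (the +F convention); ``'model'`` keeps the
    published / uniform frequencies.  GTR exchangeabilities start at 1 and
    HKY85 kappa at 2; both are free parameters refined during fitting.
    ``custom:<file>`` loads a PAML-style empirical matrix (20x20).
    """
    if freq_mode not in ("model", "observed"):
        raise DomainError(f"freq_mode must be 'model' or 'observed', not {freq_mode!r}")

    def freqs(default, alphabet):
        if freq_mode == "observed":
            if aln is None:
                raise DomainError("freq_mode='observed' requires an alignment")
            if aln.alphabet != alphabet:
                raise DomainError(
                    f"model {name} needs a {alphabet} alignment, got {aln.alphabet}"
                )
            return observed_frequencies(aln)
        return default

    if name == "JC69-nuc":
        n = 4
        S = np.ones((n, n)) - np.eye(n)
        return SubstitutionModel(name, pio.NUC_STATES, S, np.full(n, 0.25))
    if name == "JC69-prot":
        n = 20
        S = np.ones((n, n)) - np.eye(n)
        return SubstitutionModel(name, pio.PROTEIN_STATES, S, np.full(n, 0.05))
    if name == "GTR":
        S = np.ones((4, 4)) - np.eye(4)
        pi = freqs(np.full(4, 0.25), pio.NUCLEOTIDE)
        m = SubstitutionModel(name, pio.NUC_STATES, S, pi)
        m.free_params = {"rates": np.ones(5)}  # 6th exchangeability fixed at 1
        return m
    if name == "HKY85":
        kappa = 2.0
        S = hky_exchangeabilities(kappa)
        pi = freqs(np.full(4, 0.25), pio.NUCLEOTIDE)
        m = SubstitutionModel(name, pio.NUC_STATES, S, pi)
        m.free_params = {"kappa": kappa}
        return m
    if name in _EMPIRICAL_FILES:
        S, pi_model = _bundled_matrix(name)
        pi = freqs(pi_model, pio.PROTEIN)
        return SubstitutionModel(name, pio.PROTEIN_STATES, S, pi)
    if name.startswith("custom:"):
        path = name.split(":", 1)[1]
        S, pi_model = parse_paml_matrix(path)
        pi = freqs(pi_model, pio.PROTEIN)
        return SubstitutionModel(name, pio.PROTEIN_STATES, S, pi)
    raise DomainError(
        f"unknown model {name!r}; choose from "
        f"{NUCLEOTIDE_MODELS + PROTEIN_MODELS} or custom:<file>"
    )


def hky_exchangeabilities(kappa: float) -> np.ndarray:
    S = np.ones((4, 4)) - np.eye(4)
    for i, j in _HKY_TRANSITIONS:
        S[i, j] = S[j, i] = kappa
    return S


def gtr_exchangeabilities(rates: Sequence[float]) -> np.ndarray:
    """Build the GTR S matrix from 5 free rates (AC, AG, AT, CG, CT); GT = 1."""
    r = list(rates) + [1.0]
    S = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(i + 1, 4):
            S[i, j] = S[j, i] = r[k]
            k += 1
    return S


@dataclass
class RateDistribution:
    """Discrete mixture of rate categories with mean exactly one."""

    rates: np.ndarray
    weights: np.ndarray
    family: str = "none"      # none | gamma | gdd
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.rates.shape != self.weights.shape or self.rates.ndim != 1:
            raise DomainError("rates and weights must be 1-D and equal length")
        if np.any(self.rates < 0):
            raise DomainError("category rates must be >= 0")
        if np.any(self.weights <= 0):
            raise DomainError("category weights must be > 0")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise DomainError("weights must sum to 1")
        if abs(float(self.weights @ self.rates) - 1.0) > 1e-10:
            raise DomainError("mean rate must equal 1")

    @property
    def k(self) -> int:
        return len(self.rates)


def constant_rate() -> RateDistribution:
    return RateDistribution(np.array([1.0]), np.array([1.0]), family="none")


def discrete_gamma(alpha: float, k: int) -> RateDistribution:
    """Mean-one discrete gamma with k equal-weight categories.

    Category rates are the conditional means of the k equal-probability
    slabs of a Gamma(alpha, scale=1/alpha) distribution, so the mixture
    mean is exactly 1 (Yang's mean-of-bin discretization).
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise DomainError(f"gamma shape must be > 0, got {alpha}")
    k = int(k)
    if k < 1:
        raise DomainError("category count must be >= 1")
    if k == 1:
        return RateDistribution(
            np.array([1.0]), np.array([1.0]), "gamma", {"alpha": alpha, "k": 1}
        )
    # slab boundaries at gamma quantiles; slab means via the alpha+1 CDF trick:
    # E[X; a<X<b] = CDF(b; alpha+1) - CDF(a; alpha+1) for Gamma(alpha, rate=alpha)
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    cdf1 = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    cdf1 = np.concatenate([[0.0], cdf1, [1.0]])
    rates = k * np.diff(cdf1)
    rates = np.clip(rates, 0.0, None)
    rates /= rates.mean()  # remove last-digit drift from quadrature
    return RateDistribution(
        rates, np.full(k, 1.0 / k), "gamma", {"alpha": alpha, "k": k}
    )


def general_discrete(rates: Sequence[float], weights: Sequence[float]) -> RateDistribution:
    """General discrete distribution: weights renormalized, rates rescaled to mean one."""
    r = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(r < 0):
        raise DomainError("GDD rates must be >= 0")
    if np.any(w <= 0):
        raise DomainError("GDD weights must be > 0")
    w = w / w.sum()
    mean = float(w @ r)
    if mean <= 0:
        raise DomainError("GDD mean rate must be > 0")
    return RateDistribution(r / mean, w, "gdd", {"k": len(r)})
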