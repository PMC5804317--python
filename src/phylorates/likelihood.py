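"""Felsenstein pruning likelihoods with per-node numerical rescaling.

The engine works on an indexed form of the tree: tips are numbered in
alignment taxon order, internal nodes follow in postorder, and each
non-root node carries the length of the branch above it.  Conditional
likelihood vectors are renormalized (in log space) whenever their largest
entry drops below ``SCALE_THRESHOLD``, so trees with thousands of tips do
not underflow.

A zero effective branch length (including the rate-0 limit used for
invariant sites) is handled analytically with an identity transition
matrix rather than as a numerical limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from . import io as pio
from . import models
from .exceptions import BindError, DomainError

# Conditional likelihoods are renormalized whenever their per-pattern max
# drops below this, after *every* child multiplication: a single product of
# two deeply-scaled messages can reach exact zero otherwise.
SCALE_THRESHOLD = 1e-80


@dataclass
class SitePattern:
    """One alignment column: per-taxon sets of allowed states.

    ``partials`` is a (n_taxa, n_states) 0/1 matrix; a canonical character
    is a singleton row, a gap is all-ones, an ambiguity code a partial row.
    """

    taxa: list
    partials: np.ndarray

    @classmethod
    def from_characters(cls, taxa: Sequence[str], chars: Sequence[str], alphabet: str):
        sets = pio.state_sets(alphabet)
        n = len(pio.alphabet_states(alphabet))
        part = np.zeros((len(taxa), n))
        for i, c in enumerate(chars):
            c = c.upper()
            if c not in sets:
                raise DomainError(f"character {c!r} not in the {alphabet} alphabet")
            part[i, list(sets[c])] = 1.0
        return cls(list(taxa), part)

    @property
    def is_uninformative(self) -> bool:
        """True when every taxon allows every state (an all-gap column)."""
        return bool(self.partials.all())


class TreeIndex:
    """Array form of a tree bound to an ordered taxon list."""

    def __init__(self, tree: pio.Tree, taxa: Sequence[str], default_length: float = 0.1):
        taxa = list(taxa)
        tip_pos = {t: i for i, t in enumerate(taxa)}
        if set(tree.tip_labels) != set(taxa):
            raise BindError("tree tips do not match the requested taxon order")
        n_tips = len(taxa)
        dnodes = list(tree.dtree.postorder_node_iter())
        internals = [nd for nd in dnodes if not nd.is_leaf()]
        self.n_tips = n_tips
        self.n_nodes = n_tips + len(internals)
        self.root = self.n_nodes - 1
        ids = {}
        for nd in dnodes:
            if nd.is_leaf():
                ids[nd] = tip_pos[nd.taxon.label]
        for k, nd in enumerate(internals):
            ids[nd] = n_tips + k
        self.children = [[] for _ in range(self.n_nodes)]
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.lengths = np.zeros(self.n_nodes)
        self.has_input_lengths = True
        root_node = tree.dtree.seed_node
        for nd in dnodes:
            v = ids[nd]
            for ch in nd.child_nodes():
                self.children[v].append(ids[ch])
                self.parent[ids[ch]] = v
            if nd is not root_node:
                if nd.edge.length is None:
                    self.has_input_lengths = False
                    self.lengths[v] = default_length
                else:
                    self.lengths[v] = float(nd.edge.length)
        self.internal_postorder = [ids[nd] for nd in internals]
        self.taxa = taxa
        self._dnode_ids = ids
        self._tree = tree

    def nonroot_nodes(self) -> np.ndarray:
        return np.array([v for v in range(self.n_nodes) if v != self.root])

    def tree_with_lengths(self, lengths: np.ndarray) -> pio.Tree:
        """Copy of the source tree carrying the supplied branch lengths."""
        clone = self._tree.clone()
        src = {id(nd): v for nd, v in self._dnode_ids.items()}
        # clone(depth=1) preserves node correspondence via matched traversal
        for orig, copy in zip(
            self._tree.dtree.postorder_node_iter(), clone.dtree.postorder_node_iter()
        ):
            if orig is not self._tree.dtree.seed_node:
                copy.edge.length = float(lengths[self._dnode_ids[orig]])
        return clone


def encode_columns(
    columns: np.ndarray, taxa: Sequence[str], alphabet: str
) -> np.ndarray:
    """Tip partials for a (n_taxa, n_sites) character block: (n_taxa, n_sites, n)."""
    sets = pio.state_sets(alphabet)
    n = len(pio.alphabet_states(alphabet))
    lut = {}
    for c, idx in sets.items():
        row = np.zeros(n)
        row[list(idx)] = 1.0
        lut[c] = row
    out = np.zeros((columns.shape[0], columns.shape[1], n))
    for c in np.unique(columns):
        if c not in lut:
            raise DomainError(f"character {c!r} not in the {alphabet} alphabet")
        out[columns == c] = lut[c]
    return out


def compress_patterns(columns: np.ndarray):
    """Unique columns of a (n_taxa, n_sites) block.

    Returns (unique columns as (n_taxa, n_patterns), counts, inverse index).
    """
    cols = columns.T  # (n_sites, n_taxa)
    uniq, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return uniq.T, counts.astype(float), inverse


class PruningEngine:
    """Vectorized pruning over a fixed pattern block.

    ``tip_partials`` has shape (n_tips, n_patterns, n_states).  Branch
    lengths live on the engine and may be overwritten between evaluations.
    """

    def __init__(
        self,
        index: TreeIndex,
        model: models.SubstitutionModel,
        tip_partials: np.ndarray,
    ):
        if tip_partials.shape[0] != index.n_tips:
            raise BindError("tip partial block does not match the tree")
        if tip_partials.shape[2] != model.n_states:
            raise BindError("pattern alphabet does not match the model")
        self.index = index
        self.model = model
        self.tip_partials = np.asarray(tip_partials, dtype=float)
        self.n_patterns = tip_partials.shape[1]
        self.lengths = index.lengths.copy()

    def set_model(self, model: models.SubstitutionModel) -> None:
        self.model = model

    def _tmats(self, ts: np.ndarray) -> np.ndarray:
        P = models.transition_matrices(self.model, ts)
        zero = ts == 0.0
        if np.any(zero):
            P[zero] = np.eye(self.model.n_states)
        return P

    def site_log_likelihoods(
        self, rate: float = 1.0, lengths: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Per-pattern log-likelihood with every branch scaled by ``rate``."""
        if rate < 0:
            raise DomainError(f"site rate scaler must be >= 0, got {rate}")
        base = self.lengths if lengths is None else lengths
        ts = base * rate
        P = self._tmats(ts)
        idx = self.index
        n = self.model.n_states
        clv = np.empty((idx.n_nodes, self.n_patterns, n))
        clv[: idx.n_tips] = self.tip_partials
        slog = np.zeros(self.n_patterns)
        for v in idx.internal_postorder:
            acc = None
            for c in idx.children[v]:
                m = clv[c] @ P[c].T
                acc = m if acc is None else acc * m
                smax = acc.max(axis=1)
                small = (smax < SCALE_THRESHOLD) & (smax > 0)
                if small.any():
                    acc[small] /= smax[small, None]
                    slog[small] += np.log(smax[small])
            clv[v] = acc
        like = clv[idx.root] @ self.model.pi
        with np.errstate(divide="ignore"):
            return np.log(like) + slog


class CachedPruner:
    """Pruning engine with cached per-node messages for fast branch updates.

    For each non-root node ``v`` the message ``msg[v] = clv[v] @ P(t_v).T``
    is cached together with the accumulated log-scaling of its subtree;
    changing one branch length then only requires recomputing the path from
    that branch to the root.
    """

    def __init__(self, engine: PruningEngine, rate: float = 1.0):
        self.e = engine
        self.rate = rate
        idx = engine.index
        n = engine.model.n_states
        self.clv = np.empty((idx.n_nodes, engine.n_patterns, n))
        self.clv[: idx.n_tips] = engine.tip_partials
        self.slog = np.zeros((idx.n_nodes, engine.n_patterns))
        self.msg = np.zeros_like(self.clv)
        self.full_update()

    def _message(self, v: int, t: float) -> np.ndarray:
        if t == 0.0:
            return self.clv[v].copy()
        P = models.transition_matrix(self.e.model, t)
        return self.clv[v] @ P.T

    @staticmethod
    def _rescale(acc: np.ndarray, slog: np.ndarray) -> None:
        smax = acc.max(axis=1)
        small = (smax < SCALE_THRESHOLD) & (smax > 0)
        if small.any():
            acc[small] /= smax[small, None]
            slog[small] += np.log(smax[small])

    def full_update(self) -> None:
        idx = self.e.index
        for v in range(idx.n_tips):
            if v != idx.root:
                self.msg[v] = self._message(v, self.e.lengths[v] * self.rate)
        for v in idx.internal_postorder:
            self._recompute_node(v)
            if v != idx.root:
                self.msg[v] = self._message(v, self.e.lengths[v] * self.rate)

    def _recompute_node(self, v: int) -> None:
        idx = self.e.index
        acc = None
        sl = np.zeros(self.e.n_patterns)
        for c in idx.children[v]:
            acc = self.msg[c].copy() if acc is None else acc * self.msg[c]
            sl += self.slog[c]
            self._rescale(acc, sl)
        self.clv[v] = acc
        self.slog[v] = sl

    def site_logliks(self) -> np.ndarray:
        idx = self.e.index
        like = self.clv[idx.root] @ self.e.model.pi
        with np.errstate(divide="ignore"):
            return np.log(like) + self.slog[idx.root]

    def branch_site_logliks(self, v: int, t: float) -> np.ndarray:
        """Per-pattern log-likelihoods with branch ``v`` trialed at length ``t``.

        The cache is not modified.
        """
        idx = self.e.index
        m = self._message(v, t * self.rate)
        sl = self.slog[v].copy()
        node = idx.parent[v]
        prev = v
        while True:
            acc = m.copy()
            sl = sl.copy()
            self._rescale(acc, sl)
            for c in idx.children[node]:
                if c != prev:
                    acc = acc * self.msg[c]
                    sl = sl + self.slog[c]
                    self._rescale(acc, sl)
            if node == idx.root:
                like = acc @ self.e.model.pi
                with np.errstate(divide="ignore"):
                    return np.log(like) + sl
            m = self._message_from(acc, self.e.lengths[node] * self.rate)
            prev = node
            node = idx.parent[node]

    def _message_from(self, clv: np.ndarray, t: float) -> np.ndarray:
        if t == 0.0:
            return clv
        P = models.transition_matrix(self.e.model, t)
        return clv @ P.T

    def commit_branch(self, v: int, t: float) -> None:
        idx = self.e.index
        self.e.lengths[v] = t
        self.msg[v] = self._message(v, t * self.rate)
        node = idx.parent[v]
        while node != -1:
            self._recompute_node(node)
            if node != idx.root:
                self.msg[node] = self._message(node, self.e.lengths[node] * self.rate)
            node = idx.parent[node]

    def refresh(self) -> None:
        """Rebuild all caches (after a model or wholesale length change)."""
        self.full_update()


def site_log_likelihood(
    tree: pio.Tree,
    model: models.SubstitutionModel,
    pattern: SitePattern,
    r: float = 1.0,
) -> float:
    """Log-likelihood of a single column with all branch lengths scaled by r."""
    if r < 0:
        raise DomainError(f"site rate scaler must be >= 0, got {r}")
    index = TreeIndex(tree, pattern.taxa)
    engine = PruningEngine(index, model, pattern.partials[:, None, :])
    return float(engine.site_log_likelihoods(rate=r)[0])


def partition_log_likelihood(
    tree: pio.Tree,
    model: models.SubstitutionModel,
    columns: np.ndarray,
    taxa: Sequence[str],
    alphabet: str,
    rate_dist: Optional[models.RateDistribution] = None,
    lengths: Optional[np.ndarray] = None,
    site_rates: Optional[np.ndarray] = None,
) -> float:
    """Total log-likelihood of a character block (n_taxa, n_sites).

    Identical columns are computed once (pattern compression).  With a rate
    distribution, each site's likelihood is the weighted mixture over
    categories; with per-site rate scalers, each site uses its own scaler.
    """
    index = TreeIndex(tree, taxa)
    if site_rates is not None:
        site_rates = np.asarray(site_rates, dtype=float)
        total = 0.0
        for r in np.unique(site_rates):
            sel = site_rates == r
            pats, counts, _ = compress_patterns(columns[:, sel])
            eng = PruningEngine(index, model, encode_columns(pats, taxa, alphabet))
            if lengths is not None:
                eng.lengths = np.asarray(lengths, dtype=float)
            total += float(counts @ eng.site_log_likelihoods(rate=float(r)))
        return total
    pats, counts, _ = compress_patterns(columns)
    eng = PruningEngine(index, model, encode_columns(pats, taxa, alphabet))
    if lengths is not None:
        eng.lengths = np.asarray(lengths, dtype=float)
    if rate_dist is None or rate_dist.k == 1 and rate_dist.rates[0] == 1.0:
        return float(counts @ eng.site_log_likelihoods(rate=1.0))
    per_cat = np.stack(
        [eng.site_log_likelihoods(rate=float(r)) for r in rate_dist.rates]
    )
    site_ll = logsumexp(per_cat + np.log(rate_dist.weights)[:, None], axis=0)
    return float(counts @ site_ll)
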