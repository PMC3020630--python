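"""Amino-acid substitution models and tree likelihoods.

Implements the Dayhoff and WAG empirical models as general
time-reversible rate matrices Q_ij = s_ij * pi_j (s symmetric), scaled to
one expected substitution per site at stationarity, with discrete-gamma
rate heterogeneity across sites (equal-probability categories represented
by their conditional means).  On top of these: transition matrices by
symmetric eigendecomposition, pairwise maximum-likelihood distances,
per-site log-likelihoods on trees by Felsenstein pruning, and
coordinate-wise branch-length optimization.

Branch lengths are expected substitutions per site.  'X' and '-' are
treated as missing data and marginalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from ._rate_tables import (AA_ORDER, DAYHOFF_FREQS, DAYHOFF_LOWER_TRIANGLE,
                           WAG_FREQS, WAG_LOWER_TRIANGLE)
from .seqio import Alignment

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
MISSING = 20  # encoding for X / gap

BRANCH_FLOOR = 1e-8
BRANCH_CEIL = 20.0

_TABLES = {
    "dayhoff": (DAYHOFF_LOWER_TRIANGLE, DAYHOFF_FREQS),
    "wag": (WAG_LOWER_TRIANGLE, WAG_FREQS),
}


@dataclass(frozen=True)
class SiteRates:
    """Discrete-gamma site-rate categories (equal probability 1/k)."""

    rates: tuple

    @property
    def k(self) -> int:
        return len(self.rates)

    @property
    def probs(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)


def discretize_gamma(alpha: float, k: int) -> SiteRates:
    """Equal-probability gamma categories by their conditional means.

    The gamma has shape *alpha* and mean 1; category i is represented by
    the mean of the distribution conditional on falling between the
    i/k and (i+1)/k quantiles, so the category means average to 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return SiteRates((1.0,))
    # conditional mean of Gamma(a, scale=1/a) between quantiles, via the
    # identity E[X; X<q] = F_{a+1}(q) for the mean-1 parameterization
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cum)
    return SiteRates(tuple(float(r) for r in rates))


class RateModel:
    """Empirical reversible amino-acid model with gamma rate mixture."""

    def __init__(self, name: str = "dayhoff", alpha: float = 1.0, k: int = 4):
        name = name.lower()
        if name not in _TABLES:
            raise ValueError(f"unknown model {name!r}; choose dayhoff or wag")
        self.name = name
        lower, freqs = _TABLES[name]
        s = np.zeros((20, 20))
        idx = 0
        for i in range(1, 20):
            for j in range(i):
                s[i, j] = s[j, i] = lower[idx]
                idx += 1
        self.exchangeabilities = s
        self.freqs = np.asarray(freqs, dtype=float)
        self.freqs = self.freqs / self.freqs.sum()
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # scale to one expected substitution per site at stationarity
        mean_rate = -(self.freqs * np.diag(q)).sum()
        self.Q = q / mean_rate
        # symmetric eigendecomposition: B = D^1/2 Q D^-1/2 is symmetric
        sqrtpi = np.sqrt(self.freqs)
        b = (sqrtpi[:, None] * self.Q) / sqrtpi[None, :]
        evals, evecs = np.linalg.eigh((b + b.T) / 2)
        self._evals = evals
        self._left = evecs / sqrtpi[:, None] * 1.0   # D^-1/2 U
        self._right = (evecs * sqrtpi[:, None]).T    # U^T D^1/2
        self.site_rates = discretize_gamma(alpha, k)
        self.alpha = alpha
        self.k = k

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q t rate); rows sum to one."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._left * np.exp(self._evals * t * rate)) @ self._right
        return np.clip(p, 0.0, None)

    def category_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r_c) over the gamma categories, shape (k,20,20)."""
        return np.stack([self.transition_matrix(t, r) for r in self.site_rates.rates])


def transition_matrix(model: RateModel, t: float, rate: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate)


def encode_sequence(residues: str) -> np.ndarray:
    return np.array([AA_INDEX.get(c, MISSING) for c in residues], dtype=np.int64)


def ml_pair_distance(a: str, b: str, model: RateModel,
                     t_max: float = BRANCH_CEIL, tol: float = 1e-6) -> float:
    """Maximum-likelihood distance between two aligned sequences.

    Columns where either sequence is missing ('X' or '-') are skipped
    pairwise.  The likelihood mixes over the model's gamma categories.
    """
    xa, xb = encode_sequence(a), encode_sequence(b)
    if len(xa) != len(xb):
        raise ValueError("sequences must be aligned to equal length")
    keep = (xa != MISSING) & (xb != MISSING)
    if not keep.any():
        raise ValueError("no shared non-missing columns")
    counts = np.zeros((20, 20))
    np.add.at(counts, (xa[keep], xb[keep]), 1.0)

    rates = np.array(model.site_rates.rates)

    def neg_loglik(t: float) -> float:
        mix = np.zeros((20, 20))
        for r in rates:
            mix += model.transition_matrix(t, r)
        mix /= len(rates)
        joint = model.freqs[:, None] * mix
        return -float((counts * np.log(np.maximum(joint, 1e-300))).sum())

    res = minimize_scalar(neg_loglik, bounds=(BRANCH_FLOOR, t_max),
                          method="bounded", options={"xatol": tol})
    return float(res.x)


class TreeLikelihood:
    """Felsenstein pruning over a dendropy tree with gamma mixture.

    Holds a postorder array representation of the tree; edge lengths are
    read from (and written back to) the dendropy edges so callers can
    keep using the tree object.
    """

    def __init__(self, tree: dendropy.Tree, alignment: Alignment,
                 model: RateModel):
        self.tree = tree
        self.model = model
        seqs = {r.id: r.residues for r in alignment.records}
        self.n_sites = alignment.n_columns

        self.postorder = list(tree.postorder_node_iter())
        self.node_index = {id(n): i for i, n in enumerate(self.postorder)}
        self.children = []
        self.tip_states = {}
        for i, node in enumerate(self.postorder):
            kids = node.child_nodes()
            self.children.append([self.node_index[id(c)] for c in kids])
            if not kids:
                label = node.taxon.label if node.taxon else None
                if label not in seqs:
                    raise ValueError(f"tree tip {label!r} missing from alignment")
                self.tip_states[i] = encode_sequence(seqs[label])
        self.root = len(self.postorder) - 1
        self.edge_nodes = [n for n in self.postorder[:-1]]
        # per-edge cache of (length, P-matrices, tip contribution); during
        # single-branch optimization only one edge changes per evaluation
        self._edge_cache: dict[int, tuple] = {}

    # -- edge length plumbing -------------------------------------------
    def get_lengths(self) -> np.ndarray:
        return np.array([n.edge.length if n.edge.length is not None else 0.1
                         for n in self.edge_nodes])

    def set_length(self, i: int, value: float) -> None:
        self.edge_nodes[i].edge.length = float(value)

    # -- likelihood ------------------------------------------------------
    def site_log_likelihoods(self) -> np.ndarray:
        k = self.model.k
        ns = self.n_sites
        partials = [None] * len(self.postorder)
        logscale = np.zeros(ns)
        for i, node in enumerate(self.postorder):
            kids = self.children[i]
            if not kids:
                continue
            part = np.ones((k, 20, ns))
            for c in kids:
                t = self.postorder[c].edge.length or 0.0
                cached = self._edge_cache.get(c)
                if cached is not None and cached[0] == t:
                    pmats, tip_contrib = cached[1], cached[2]
                else:
                    pmats = self.model.category_matrices(t)  # (k,20,20)
                    tip_contrib = None
                if c in self.tip_states:
                    if tip_contrib is None:
                        states = self.tip_states[c]
                        tip_contrib = np.ones((k, 20, ns))
                        obs = states != MISSING
                        tip_contrib[:, :, obs] = pmats[:, :, states[obs]]
                    contrib = tip_contrib
                else:
                    contrib = np.einsum("kxy,kys->kxs", pmats, partials[c])
                self._edge_cache[c] = (t, pmats, tip_contrib)
                part *= contrib
            smax = part.max(axis=(0, 1))
            smax = np.where(smax > 0, smax, 1.0)
            part /= smax
            logscale += np.log(smax)
            partials[i] = part
        root = partials[self.root]
        site_l = np.einsum("x,kxs->s", self.model.freqs, root) / self.model.k
        return np.log(np.maximum(site_l, 1e-300)) + logscale

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    def optimize_branch_lengths(self, tol: float = 1e-4, max_iter: int = 50,
                                sweeps: int | None = None) -> tuple[float, bool]:
        """Coordinate-wise Brent optimization of all edge lengths.

        Iterates full sweeps until the log-likelihood improves by less
        than *tol* (or *sweeps* sweeps have run); returns (logL,
        converged flag).  The log-likelihood never decreases.
        """
        best = self.log_likelihood()
        converged = False
        n_sweeps = sweeps if sweeps is not None else max_iter
        for _ in range(n_sweeps):
            sweep_start = best
            for i in range(len(self.edge_nodes)):
                current = self.edge_nodes[i].edge.length or BRANCH_FLOOR

                def neg(t: float, i=i) -> float:
                    self.set_length(i, t)
                    return -self.log_likelihood()

                res = minimize_scalar(neg, bounds=(BRANCH_FLOOR, BRANCH_CEIL),
                                      method="bounded",
                                      options={"xatol": 1e-4})
                if -res.fun >= best:
                    self.set_length(i, res.x)
                    best = -res.fun
                else:  # numerical no-improvement: keep previous length
                    self.set_length(i, current)
            if sweeps is None and best - sweep_start < tol:
                converged = True
                break
        return best, converged


def site_log_likelihoods(alignment: Alignment, tree: dendropy.Tree,
                         model: RateModel) -> np.ndarray:
    """Per-column log-likelihoods of *alignment* on *tree* under *model*."""
    return TreeLikelihood(tree, alignment, model).site_log_likelihoods()


def optimize_branch_lengths(tree: dendropy.Tree, alignment: Alignment,
                            model: RateModel, tol: float = 1e-4,
                            max_iter: int = 50,
                            sweeps: int | None = None):
    """Optimize the tree's branch lengths in place; return (tree, logL)."""
    tl = TreeLikelihood(tree, alignment, model)
    logl, converged = tl.optimize_branch_lengths(tol=tol, max_iter=max_iter,
                                                 sweeps=sweeps)
    if not converged and sweeps is None:
        import warnings
        warnings.warn("branch-length optimization did not converge")
    return tree, logl


def estimate_gamma_alpha(alignment: Alignment, tree: dendropy.Tree,
                         model_name: str = "dayhoff", k: int = 4,
                         bounds: tuple[float, float] = (0.05, 20.0)) -> float:
    """One-dimensional ML estimate of the gamma shape on a fixed tree."""

    def neg(alpha: float) -> float:
        m = RateModel(model_name, alpha=alpha, k=k)
        return -float(site_log_likelihoods(alignment, tree, m).sum())

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)
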