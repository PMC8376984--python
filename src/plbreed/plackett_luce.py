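"""Plackett-Luce worth estimation for grouped rankings.

The Plackett-Luce model assigns each item i a positive *worth* alpha_i.
A full ordering is generated stagewise: at each stage the next-best item
is chosen among the remaining ones with probability alpha_i / sum(alpha
over remaining).  Under the sum-to-one gauge the normalized worth of an
item equals its probability of winning against all others in the set.

Two fitters are provided:

* :func:`fit_pl` -- maximum likelihood via Hunter's minorize-maximize
  (MM) iteration, which is monotone in the likelihood.  Requires the
  win/loss comparison graph to be strongly connected.
* :func:`fit_pl_genomic` -- maximum a posteriori with a multivariate
  normal prior on mean-centred log-worths whose covariance is
  proportional to a genomic (additive) relationship matrix.  The prior
  regularizes the fit and keeps it identifiable even on disconnected
  comparison graphs, mirroring the use of SNP data as a prior on
  genotype worths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
import scipy.sparse.csgraph

from .rankings import RankingSet

__all__ = [
    "WorthVector",
    "PLFit",
    "IdentifiabilityError",
    "log_likelihood",
    "fit_pl",
    "fit_pl_genomic",
    "sample_orderings",
]

_GAUGE_TOL = 1e-10


class IdentifiabilityError(ValueError):
    """Comparison graph not strongly connected: the PL MLE does not exist."""

    def __init__(self, components: list[list[str]]):
        self.components = components
        super().__init__(
            "comparison graph is not strongly connected; components: "
            + "; ".join(",".join(c) for c in components)
        )


@dataclass(frozen=True)
class WorthVector:
    """Positive per-item worths normalized to sum to one."""

    items: tuple[str, ...]
    worths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.worths, dtype=float)
        object.__setattr__(self, "worths", w)
        if len(self.items) != w.size:
            raise ValueError("items and worths length mismatch")
        if np.any(w <= 0):
            raise ValueError("all worths must be > 0")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("worths must sum to 1")

    @classmethod
    def from_unnormalized(cls, items: Sequence[str], values: np.ndarray) -> "WorthVector":
        v = np.asarray(values, dtype=float)
        return cls(tuple(items), v / v.sum())

    @classmethod
    def from_log(cls, items: Sequence[str], log_worths: np.ndarray) -> "WorthVector":
        lw = np.asarray(log_worths, dtype=float)
        v = np.exp(lw - lw.max())
        return cls(tuple(items), v / v.sum())

    @property
    def log_worths(self) -> np.ndarray:
        return np.log(self.worths)

    def as_series(self) -> pd.Series:
        return pd.Series(self.worths, index=list(self.items), name="worth")

    def __getitem__(self, item: str) -> float:
        return float(self.worths[self.items.index(item)])

    def restrict(self, items: Sequence[str]) -> "WorthVector":
        idx = [self.items.index(i) for i in items]
        return WorthVector.from_unnormalized(list(items), self.worths[idx])

    def ordering(self) -> tuple[str, ...]:
        """Best-first ordering implied by the worths; exact ties broken by
        item id (lexicographic)."""
        return tuple(sorted(self.items, key=lambda it: (-self[it], it)))


@dataclass(frozen=True)
class PLFit:
    worths: WorthVector
    log_likelihood: float
    n_iterations: int
    converged: bool

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood


# ---------------------------------------------------------------------------
# Likelihood machinery on the dense array representation
# ---------------------------------------------------------------------------

def _loglik_arrays(orderings: np.ndarray, weights: np.ndarray, log_alpha: np.ndarray) -> float:
    """Sum over records of weight * sum over stages of
    [log alpha_(chosen) - log sum(alpha over remaining)]."""
    n, m = orderings.shape
    total = 0.0
    la = np.append(log_alpha, -np.inf)  # pad index -1
    lam = la[orderings]
    mask = orderings >= 0
    lam = np.where(mask, lam, -np.inf)
    # suffix logsumexp over stages
    for k in range(m - 1):
        tail = lam[:, k:]
        tmax = tail.max(axis=1)
        finite = tmax > -np.inf
        lse = np.full(n, -np.inf)
        lse[finite] = tmax[finite] + np.log(
            np.exp(tail[finite] - tmax[finite, None]).sum(axis=1)
        )
        stage_ok = mask[:, k] & (mask[:, k:].sum(axis=1) >= 2)
        total += float(np.sum(weights[stage_ok] * (lam[stage_ok, k] - lse[stage_ok])))
    return total


def _grad_arrays(orderings: np.ndarray, weights: np.ndarray, log_alpha: np.ndarray) -> np.ndarray:
    """Gradient of the log-likelihood with respect to log-worths."""
    n, m = orderings.shape
    alpha = np.exp(log_alpha - log_alpha.max())
    a = np.append(alpha, 0.0)
    amat = a[orderings]
    # wins minus expected stage-win probabilities
    grad = np.zeros(log_alpha.size)
    for k in range(m - 1):
        tail_idx = orderings[:, k:]
        tail = amat[:, k:]
        denom = tail.sum(axis=1)
        stage_ok = (orderings[:, k] >= 0) & ((tail_idx >= 0).sum(axis=1) >= 2)
        if not stage_ok.any():
            continue
        w = weights[stage_ok]
        np.add.at(grad, orderings[stage_ok, k], w)
        frac = tail[stage_ok] / denom[stage_ok, None] * w[:, None]
        idx = tail_idx[stage_ok]
        np.subtract.at(grad, idx[idx >= 0], frac[idx >= 0])
    return grad


def _strongly_connected(orderings: np.ndarray, n_items: int) -> list[np.ndarray] | None:
    """Return None if the win digraph over items 0..n_items-1 is strongly
    connected, else the list of component index arrays."""
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    n, m = orderings.shape
    for i in range(m):
        for j in range(i + 1, m):
            ok = (orderings[:, i] >= 0) & (orderings[:, j] >= 0)
            rows.append(orderings[ok, i])
            cols.append(orderings[ok, j])
    r = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
    c = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
    adj = scipy.sparse.coo_matrix(
        (np.ones(r.size), (r, c)), shape=(n_items, n_items)
    ).tocsr()
    ncomp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    if ncomp == 1:
        return None
    return [np.flatnonzero(labels == k) for k in range(ncomp)]


def log_likelihood(r: RankingSet, w: WorthVector) -> float:
    """Plackett-Luce log-likelihood of the rankings under the given worths.

    Items in ``r`` must all have a worth; single-item rankings contribute 0.
    """
    missing = set(r.ranked_items()) - set(w.items)
    if missing:
        raise ValueError(f"items without worths: {sorted(missing)}")
    orderings, weights = r.to_arrays(items=w.items)
    return _loglik_arrays(orderings, weights, w.log_worths)


def _fit_mm(
    orderings: np.ndarray,
    weights: np.ndarray,
    n_items: int,
    tol: float,
    max_iter: int,
    init: np.ndarray | None = None,
    smoothing: float = 0.0,
) -> tuple[np.ndarray, int, bool]:
    """Hunter's MM iteration on the dense stage representation.

    ``smoothing`` > 0 adds a Gamma-style pseudo-count of wins/losses
    against a ghost opponent of average worth, which keeps the iteration
    well-defined on comparison graphs that are not strongly connected
    (update: alpha_i <- (W_i + s) / (C_i + s / (alpha_i + 1/n))).
    Returns (normalized worths, n_iterations, converged).
    """
    n, m = orderings.shape
    # wins per item and per-stage index structures (fixed across iterations)
    wins = np.zeros(n_items)
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for k in range(m - 1):
        tail_idx = orderings[:, k:]
        stage_ok = (orderings[:, k] >= 0) & ((tail_idx >= 0).sum(axis=1) >= 2)
        if not stage_ok.any():
            continue
        chosen = orderings[stage_ok, k]
        sets = tail_idx[stage_ok]
        wts = weights[stage_ok]
        np.add.at(wins, chosen, wts)
        valid = sets >= 0
        flat_ids = sets[valid]
        row_of = np.broadcast_to(
            np.arange(sets.shape[0])[:, None], sets.shape
        )[valid]
        groups.append((sets, wts, flat_ids, row_of))
    alpha = np.full(n_items, 1.0 / n_items) if init is None else init / init.sum()
    alpha = np.clip(alpha, 1e-300, None)
    converged = False
    it = 0
    a_pad = np.empty(n_items + 1)
    for it in range(1, max_iter + 1):
        a_pad[:n_items] = alpha
        a_pad[n_items] = 0.0
        denom_contrib = np.zeros(n_items)
        for sets, wts, flat_ids, row_of in groups:
            d = a_pad[sets].sum(axis=1)
            contrib = wts / d
            denom_contrib += np.bincount(
                flat_ids, weights=contrib[row_of], minlength=n_items
            )
        if smoothing > 0:
            num = wins + smoothing
            den = denom_contrib + smoothing / (alpha + 1.0 / n_items)
            new = num / den
        else:
            new = np.where(
                denom_contrib > 0,
                wins / np.where(denom_contrib > 0, denom_contrib, 1.0),
                alpha,
            )
        new = new / new.sum()
        delta = np.abs(new - alpha).max()
        alpha = new
        if delta < tol:
            converged = True
            break
    return alpha, it, converged


def fit_pl(
    r: RankingSet,
    tol: float = 1e-10,
    max_iter: int = 5000,
    init: WorthVector | None = None,
) -> PLFit:
    """Maximum-likelihood Plackett-Luce fit (MM algorithm).

    Raises :class:`IdentifiabilityError` if the comparison graph is not
    strongly connected.  Non-convergence within ``max_iter`` is flagged
    (the best iterate is returned).
    """
    items = r.ranked_items()
    if not items:
        raise ValueError("empty RankingSet")
    orderings, weights = r.to_arrays(items=items)
    comps = _strongly_connected(orderings, len(items))
    if comps is not None:
        raise IdentifiabilityError([[items[i] for i in comp] for comp in comps])
    init_arr = None
    if init is not None:
        init_arr = np.array([init[i] if i in init.items else 1.0 / len(items) for i in items])
    alpha, n_iter, converged = _fit_mm(orderings, weights, len(items), tol, max_iter, init_arr)
    wv = WorthVector.from_unnormalized(items, alpha)
    ll = _loglik_arrays(orderings, weights, wv.log_worths)
    return PLFit(worths=wv, log_likelihood=ll, n_iterations=n_iter, converged=converged)


def fit_pl_genomic(
    r: RankingSet,
    K: pd.DataFrame,
    prior_scale: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    ridge: float = 1e-8,
) -> PLFit:
    """MAP Plackett-Luce fit with a genomic-relationship prior.

    Log-worths lambda (mean-centred) get a N(0, prior_scale*K + ridge*I)
    prior; the objective maximized is ``log_likelihood - 0.5 * lambda' *
    Sigma^-1 * lambda``.  Identifiable even on disconnected comparison
    graphs, and yields worths for items that are never ranked (shrunk
    toward relatives through K).
    """
    if prior_scale <= 0:
        raise ValueError("prior_scale must be > 0")
    items = tuple(str(i) for i in K.index)
    if list(K.index) != list(K.columns):
        raise ValueError("K must have identical row and column labels")
    Kv = K.to_numpy(dtype=float)
    if not np.allclose(Kv, Kv.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    eigmin = float(np.linalg.eigvalsh(Kv).min())
    if eigmin < -1e-8:
        raise ValueError(f"K is not positive semi-definite (min eigenvalue {eigmin:.3g})")
    missing = set(r.ranked_items()) - set(items)
    if missing:
        raise ValueError(f"ranked items missing from K: {sorted(missing)}")

    n = len(items)
    sigma = prior_scale * Kv + ridge * np.eye(n)
    # larger jitter for numerically safe inversion of near-singular K
    cho = scipy.linalg.cho_factor(sigma + 1e-10 * np.eye(n))
    orderings, weights = r.to_arrays(items=items)

    def precision_dot(lam: np.ndarray) -> np.ndarray:
        return scipy.linalg.cho_solve(cho, lam)

    def objective(z: np.ndarray) -> tuple[float, np.ndarray]:
        lam = z - z.mean()
        ll = _loglik_arrays(orderings, weights, lam)
        pl = precision_dot(lam)
        f = -ll + 0.5 * float(lam @ pl)
        g_lam = -_grad_arrays(orderings, weights, lam) + pl
        g = g_lam - g_lam.mean()
        return f, g

    res = scipy.optimize.minimize(
        objective,
        x0=np.zeros(n),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    lam = res.x - res.x.mean()
    wv = WorthVector.from_log(items, lam)
    ll = _loglik_arrays(orderings, weights, lam)
    return PLFit(
        worths=wv,
        log_likelihood=ll,
        n_iterations=int(res.nit),
        converged=bool(res.success),
    )


def sample_orderings(
    log_worths: np.ndarray,
    entry_indices: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample Plackett-Luce orderings via the Gumbel-argmax construction.

    ``entry_indices`` is (n_sets, k): item indices per comparison set.
    Adding i.i.d. Gumbel noise to each entry's log-worth and sorting in
    decreasing order draws exactly from the sequential Luce process
    (winner with probability alpha_i / sum alpha among remaining).
    Returns (n_sets, k) of item indices, best first.
    """
    lw = np.asarray(log_worths, dtype=float)
    g = rng.gumbel(size=entry_indices.shape)
    scores = lw[entry_indices] + g
    order = np.argsort(-scores, axis=1)
    return np.take_along_axis(entry_indices, order, axis=1)
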