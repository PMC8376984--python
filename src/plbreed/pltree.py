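"""Plackett-Luce trees: recursive partitioning of rankings on covariates.

A PL tree recursively splits the set of ranking records by thresholding a
numeric covariate (records with covariate <= threshold go left, > goes
right) and fits a separate worth vector in every leaf, capturing
genotype-by-environment interaction as covariate-dependent worths.

Splits are gated by a Bonferroni-adjusted likelihood-ratio chi-square
test at a significance level ``alpha`` (default 0.01) and a minimum leaf
size expressed as a fraction of the *total* training records (default
0.20).  Candidate thresholds are the midpoints between consecutive unique
covariate values.  When a kinship matrix is supplied, leaf worths are
refit by the genomic MAP estimator so every genotype in the kinship gets
a worth even in leaves where it was never ranked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .plackett_luce import (
    IdentifiabilityError,
    PLFit,
    WorthVector,
    _fit_mm,
    _loglik_arrays,
    _strongly_connected,
    fit_pl_genomic,
)
from .rankings import RankingSet

__all__ = ["PLTree", "Leaf", "Split", "split_search", "split_test", "grow_tree", "predict_worths"]

NO_SPLIT = None  # sentinel returned by split_search


@dataclass
class Leaf:
    fit: PLFit
    n_records: int
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return True


@dataclass
class Split:
    covariate: str
    threshold: float
    left: "Split | Leaf"
    right: "Split | Leaf"
    n_records: int
    gain: float
    p_value: float
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return False


@dataclass
class PLTree:
    root: Split | Leaf
    alpha: float
    min_size: float
    covariates: tuple[str, ...]
    n_records: int

    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def split_covariates(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            if not node.is_leaf:
                if node.covariate not in out:
                    out.append(node.covariate)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def route(self, row) -> Leaf:
        """Route one covariate row (mapping/Series) to its leaf.
        The convention is <= goes left, > goes right."""
        node = self.root
        while not node.is_leaf:
            if node.covariate not in row:
                raise KeyError(f"missing split covariate {node.covariate!r}")
            x = float(row[node.covariate])
            node = node.left if x <= node.threshold else node.right
        return node

    def log_likelihood(self) -> float:
        return sum(leaf.fit.log_likelihood for leaf in self.leaves())

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def encode(node):
            if node.is_leaf:
                return {
                    "kind": "leaf",
                    "node_id": node.node_id,
                    "n_records": node.n_records,
                    "items": list(node.fit.worths.items),
                    "worths": [float(w) for w in node.fit.worths.worths],
                    "log_likelihood": node.fit.log_likelihood,
                }
            return {
                "kind": "split",
                "node_id": node.node_id,
                "covariate": node.covariate,
                "threshold": node.threshold,
                "n_records": node.n_records,
                "gain": node.gain,
                "p_value": node.p_value,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return json.dumps(
            {
                "alpha": self.alpha,
                "min_size": self.min_size,
                "covariates": list(self.covariates),
                "n_records": self.n_records,
                "root": encode(self.root),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PLTree":
        data = json.loads(text)

        def decode(node):
            if node["kind"] == "leaf":
                wv = WorthVector.from_unnormalized(node["items"], np.array(node["worths"]))
                fit = PLFit(
                    worths=wv,
                    log_likelihood=float(node["log_likelihood"]),
                    n_iterations=0,
                    converged=True,
                )
                return Leaf(fit=fit, n_records=int(node["n_records"]), node_id=int(node["node_id"]))
            return Split(
                covariate=node["covariate"],
                threshold=float(node["threshold"]),
                left=decode(node["left"]),
                right=decode(node["right"]),
                n_records=int(node["n_records"]),
                gain=float(node["gain"]),
                p_value=float(node["p_value"]),
                node_id=int(node["node_id"]),
            )

        return cls(
            root=decode(data["root"]),
            alpha=float(data["alpha"]),
            min_size=float(data["min_size"]),
            covariates=tuple(data["covariates"]),
            n_records=int(data["n_records"]),
        )


# ---------------------------------------------------------------------------
# Split machinery
# ---------------------------------------------------------------------------

def _candidate_thresholds(x: np.ndarray, max_candidates: int | None) -> np.ndarray:
    uniq = np.unique(x)
    if uniq.size < 2:
        return np.empty(0)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if max_candidates is not None and mids.size > max_candidates:
        idx = np.unique(np.round(np.linspace(0, mids.size - 1, max_candidates)).astype(int))
        mids = mids[idx]
    return mids


def _fittable(orderings: np.ndarray, n_items: int) -> bool:
    """MLE existence for the sub-sample: the items present must form one
    strongly connected win component."""
    present = np.unique(orderings[orderings >= 0])
    remap = -np.ones(n_items + 1, dtype=np.int64)
    remap[present] = np.arange(present.size)
    sub = remap[orderings]
    return _strongly_connected(sub, present.size) is None


def _node_loglik(orderings, weights, n_items, init, tol, max_iter, smoothing=0.0):
    alpha, _, _ = _fit_mm(orderings, weights, n_items, tol, max_iter, init, smoothing)
    ll = _loglik_arrays(orderings, weights, np.log(np.clip(alpha, 1e-300, None)))
    return alpha, ll


def _best_split_for_covariate(
    orderings: np.ndarray,
    weights: np.ndarray,
    x: np.ndarray,
    n_items: int,
    parent_alpha: np.ndarray,
    parent_ll: float,
    min_count: int,
    max_candidates: int | None,
    tol: float,
    max_iter: int,
    smoothing: float = 0.0,
    require_connected: bool = True,
) -> tuple[float, float, int] | None:
    """Best (threshold, gain, n_candidates) for one covariate, or None.

    ``require_connected`` skips candidate splits whose children have a
    disconnected win graph (needed when leaves will be pure-MLE fits);
    with a smoothed fit and genomic leaf estimates it can be relaxed.
    """
    mids = _candidate_thresholds(x, max_candidates)
    if mids.size == 0:
        return NO_SPLIT
    best: tuple[float, float] | None = None
    left_init = parent_alpha.copy()
    right_init = parent_alpha.copy()
    for t in mids:
        left_mask = x <= t
        n_left = int(left_mask.sum())
        n_right = x.size - n_left
        if n_left < min_count or n_right < min_count:
            continue
        ol, wl = orderings[left_mask], weights[left_mask]
        orr, wr = orderings[~left_mask], weights[~left_mask]
        if require_connected and (
            not _fittable(ol, n_items) or not _fittable(orr, n_items)
        ):
            continue
        left_init, ll_l = _node_loglik(ol, wl, n_items, left_init, tol, max_iter, smoothing)
        right_init, ll_r = _node_loglik(orr, wr, n_items, right_init, tol, max_iter, smoothing)
        gain = max(0.0, (ll_l + ll_r) - parent_ll)
        if best is None or gain > best[1]:
            best = (float(t), gain)
    if best is None:
        return NO_SPLIT
    return best[0], best[1], mids.size


def split_search(
    r: RankingSet,
    cov: pd.DataFrame,
    covariate: str,
    min_size: float = 0.20,
    max_candidates: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 2000,
    smoothing: float = 0.0,
    require_connected: bool = True,
) -> tuple[float, float] | None:
    """Search the best threshold for one covariate on the full RankingSet.

    Returns ``(threshold, log-likelihood gain)`` where gain =
    (LL_left + LL_right) - LL_parent >= 0, maximized over the midpoints of
    consecutive unique covariate values subject to both children holding
    at least ``min_size`` of the records.  Returns ``None`` when no
    admissible split exists.
    """
    items = r.ranked_items()
    orderings, weights = r.to_arrays(items=items)
    x = _covariate_values(r, cov, covariate)
    n_items = len(items)
    min_count = int(np.ceil(min_size * len(r)))
    parent_alpha, parent_ll = _node_loglik(
        orderings, weights, n_items, None, tol, max_iter, smoothing
    )
    res = _best_split_for_covariate(
        orderings, weights, x, n_items, parent_alpha, parent_ll,
        min_count, max_candidates, tol, max_iter, smoothing, require_connected,
    )
    if res is NO_SPLIT:
        return NO_SPLIT
    return res[0], res[1]


def split_test(gain: float, n_thresholds: int, n_covariates: int, df: int) -> float:
    """Bonferroni-adjusted likelihood-ratio p-value for a candidate split.

    The LR statistic is 2*gain with ``df`` degrees of freedom (one free
    worth vector per extra leaf, gauge-fixed).  The raw chi-square upper
    tail is multiplied by the number of candidate thresholds and the
    number of covariates searched, then clipped to 1.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    p = float(scipy.stats.chi2.sf(2.0 * gain, df))
    return min(1.0, p * max(1, n_thresholds) * max(1, n_covariates))


def _covariate_values(r: RankingSet, cov: pd.DataFrame, covariate: str) -> np.ndarray:
    if covariate not in cov.columns:
        raise KeyError(f"covariate {covariate!r} not in table")
    col = cov[covariate]
    try:
        vals = np.array([float(col.loc[rec.group]) for rec in r.records])
    except KeyError as exc:
        raise KeyError(f"record group {exc} missing from covariate table") from exc
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"covariate {covariate!r} has non-finite values")
    return vals


def grow_tree(
    r: RankingSet,
    cov: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    alpha: float = 0.01,
    min_size: float = 0.20,
    kinship: pd.DataFrame | None = None,
    prior_scale: float = 1.0,
    max_candidates: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 3000,
    smoothing: float = 0.5,
    search_tol: float = 1e-6,
) -> PLTree:
    """Grow a Plackett-Luce tree by recursive significance-gated splits.

    At every node the best threshold is searched for each covariate; the
    covariate with the largest gain is tested with
    :func:`split_test` and the split accepted when the adjusted p-value is
    below ``alpha`` and both children hold at least ``min_size`` of the
    *total* records.  Leaves carry maximum-likelihood worths, or genomic
    MAP worths when ``kinship`` is given.

    Split-search fits use a light pseudo-count ``smoothing`` so that
    candidate gains remain defined on sparse children; without a kinship
    matrix candidate splits whose children have disconnected win graphs
    are still rejected (their pure-MLE leaf fit would not exist).
    """
    covariates = tuple(covariates) if covariates is not None else tuple(
        c for c in cov.columns if pd.api.types.is_numeric_dtype(cov[c])
    )
    items = r.ranked_items()
    n_items = len(items)
    orderings, weights = r.to_arrays(items=items)
    X = np.column_stack([_covariate_values(r, cov, c) for c in covariates]) if covariates else np.empty((len(r), 0))
    total = len(r)
    min_count = max(1, int(np.ceil(min_size * total)))
    counter = {"next_id": 0}

    def leaf_fit(indices: np.ndarray) -> PLFit:
        sub = r.select(list(indices))
        if kinship is not None:
            return fit_pl_genomic(sub, kinship, prior_scale=prior_scale)
        o, w = orderings[indices], weights[indices]
        present = np.unique(o[o >= 0])
        remap = -np.ones(n_items + 1, dtype=np.int64)
        remap[present] = np.arange(present.size)
        sub_o = remap[o]
        comps = _strongly_connected(sub_o, present.size)
        if comps is not None:
            raise IdentifiabilityError(
                [[items[present[i]] for i in comp] for comp in comps]
            )
        a, n_it, conv = _fit_mm(sub_o, w, present.size, tol, max_iter, None)
        wv = WorthVector.from_unnormalized([items[i] for i in present], a)
        ll = _loglik_arrays(sub_o, w, np.log(a))
        return PLFit(worths=wv, log_likelihood=ll, n_iterations=n_it, converged=conv)

    def make_leaf(indices: np.ndarray) -> Leaf:
        node = Leaf(fit=leaf_fit(indices), n_records=indices.size, node_id=counter["next_id"])
        counter["next_id"] += 1
        return node

    def build(indices: np.ndarray) -> Split | Leaf:
        o, w = orderings[indices], weights[indices]
        if indices.size < 2 * min_count or not covariates:
            return make_leaf(indices)
        if kinship is None and not _fittable(o, n_items):
            # cannot form pure-MLE leaves below a non-identifiable node
            return make_leaf(indices)
        parent_alpha, parent_ll = _node_loglik(
            o, w, n_items, None, search_tol, max_iter, smoothing
        )
        best = None  # (gain, covariate, threshold, n_cand)
        for j, cname in enumerate(covariates):
            res = _best_split_for_covariate(
                o, w, X[indices, j], n_items, parent_alpha, parent_ll,
                min_count, max_candidates, search_tol, max_iter,
                smoothing, require_connected=kinship is None,
            )
            if res is NO_SPLIT:
                continue
            t, gain, n_cand = res
            if best is None or gain > best[0] + 1e-12:
                best = (gain, cname, t, n_cand)
        if best is None:
            return make_leaf(indices)
        gain, cname, t, n_cand = best
        present = np.unique(o[o >= 0])
        p = split_test(gain, n_cand, len(covariates), df=max(1, present.size - 1))
        if p >= alpha:
            return make_leaf(indices)
        node_id = counter["next_id"]
        counter["next_id"] += 1
        j = covariates.index(cname)
        left_idx = indices[X[indices, j] <= t]
        right_idx = indices[X[indices, j] > t]
        return Split(
            covariate=cname,
            threshold=float(t),
            left=build(left_idx),
            right=build(right_idx),
            n_records=int(indices.size),
            gain=float(gain),
            p_value=float(p),
            node_id=node_id,
        )

    root = build(np.arange(total))
    return PLTree(
        root=root,
        alpha=alpha,
        min_size=min_size,
        covariates=covariates,
        n_records=total,
    )


def predict_worths(tree: PLTree, cov_rows: pd.DataFrame) -> list[WorthVector]:
    """Route each covariate row to its leaf and return the leaf's worths.

    Rows must contain every covariate the tree splits on; a row exactly at
    a threshold goes left (``<=`` convention).
    """
    out = []
    for _, row in cov_rows.iterrows():
        leaf = tree.route(row)
        out.append(leaf.fit.worths)
    return out
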