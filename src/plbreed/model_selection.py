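"""Forward covariate selection for Plackett-Luce trees.

Covariates enter the tree greedily: each candidate extension of the
current set is scored by leave-one-season-out (blocked) cross-validation
-- a tree grown on the training seasons, held-out deviance summed over
the validation season -- and candidate sets are compared through Akaike
weights computed from the mean holdout deviance plus a complexity
penalty.  A step is accepted only if the best extension's weight strictly
exceeds the incumbent set's weight; ties between candidates are broken by
covariate name order, so the procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .plackett_luce import log_likelihood
from .pltree import PLTree, grow_tree
from .rankings import RankingSet

__all__ = ["CVResult", "SelectionResult", "holdout_deviance", "akaike_weights", "forward_select"]


@dataclass
class CVResult:
    """Cross-validation summary for one candidate covariate set."""

    covariates: tuple[str, ...]
    block_deviances: dict[str, float]
    mean_deviance: float
    penalty: float
    aic: float
    akaike_weight: float = float("nan")
    accepted: bool = False
    step: int = 0


@dataclass
class SelectionResult:
    selected: tuple[str, ...]
    trail: list[CVResult]

    def trail_frame(self) -> pd.DataFrame:
        rows = []
        for cv in self.trail:
            row = {
                "step": cv.step,
                "covariates": "+".join(cv.covariates) if cv.covariates else "(null)",
                "mean_deviance": cv.mean_deviance,
                "penalty": cv.penalty,
                "aic": cv.aic,
                "akaike_weight": cv.akaike_weight,
                "accepted": cv.accepted,
            }
            for b, d in cv.block_deviances.items():
                row[f"deviance_{b}"] = d
            rows.append(row)
        return pd.DataFrame(rows)


def holdout_deviance(
    train: RankingSet,
    train_cov: pd.DataFrame,
    test: RankingSet,
    test_cov: pd.DataFrame,
    covariates: Sequence[str],
    alpha: float = 0.01,
    min_size: float = 0.20,
    kinship: pd.DataFrame | None = None,
    prior_scale: float = 1.0,
    max_candidates: int | None = None,
) -> tuple[float, PLTree]:
    """Grow a tree on the training rankings, route the held-out records
    and return (-2 * held-out log-likelihood, tree).

    With an empty covariate list the tree is root-only and the deviance is
    that of the single fitted worth vector on the test set.  A test item
    absent from a leaf's worths is an error unless a kinship matrix was
    supplied (the genomic MAP leaf fit covers every kinship genotype).
    """
    tree = grow_tree(
        train,
        train_cov,
        covariates=covariates,
        alpha=alpha,
        min_size=min_size,
        kinship=kinship,
        prior_scale=prior_scale,
        max_candidates=max_candidates,
    )
    dev = 0.0
    for rec in test.records:
        leaf = tree.route(test_cov.loc[rec.group])
        wv = leaf.fit.worths
        missing = set(rec.ordering) - set(wv.items)
        if missing:
            raise KeyError(
                f"test items {sorted(missing)} not in training worths for field "
                f"{rec.group!r}; supply a kinship matrix for genomic leaf fits"
            )
        sub = RankingSet([rec], items=wv.items)
        dev += -2.0 * log_likelihood(sub, wv)
    return dev, tree


def akaike_weights(
    mean_deviances: Sequence[float], penalty: Sequence[float]
) -> np.ndarray:
    """Akaike weights over candidate models.

    AIC_m = deviance_m + 2 * penalty_m; Delta_m = AIC_m - min AIC;
    w_m = exp(-Delta_m / 2) / sum_k exp(-Delta_k / 2).
    """
    dev = np.asarray(mean_deviances, float)
    pen = np.asarray(penalty, float)
    if dev.size == 0:
        raise ValueError("need at least one candidate")
    aic = dev + 2.0 * pen
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _cv_candidate(
    r: RankingSet,
    cov: pd.DataFrame,
    blocks: Sequence[str],
    covariates: tuple[str, ...],
    alpha: float,
    min_size: float,
    kinship: pd.DataFrame | None,
    prior_scale: float,
    max_candidates: int | None,
) -> CVResult:
    block_dev: dict[str, float] = {}
    leaves = []
    for b in blocks:
        train = r.subset(lambda rec: rec.season != b)
        test = r.subset(lambda rec: rec.season == b)
        dev, tree = holdout_deviance(
            train, cov, test, cov, covariates,
            alpha=alpha, min_size=min_size, kinship=kinship,
            prior_scale=prior_scale, max_candidates=max_candidates,
        )
        block_dev[b] = dev
        leaves.append(tree.n_leaves)
    n_items = len(r.ranked_items())
    penalty = float(np.mean(leaves)) * (n_items - 1)
    mean_dev = float(np.mean(list(block_dev.values())))
    return CVResult(
        covariates=covariates,
        block_deviances=block_dev,
        mean_deviance=mean_dev,
        penalty=penalty,
        aic=mean_dev + 2.0 * penalty,
    )


def forward_select(
    r: RankingSet,
    cov: pd.DataFrame,
    candidates: Sequence[str],
    blocks: Sequence[str] | None = None,
    alpha: float = 0.01,
    min_size: float = 0.20,
    kinship: pd.DataFrame | None = None,
    prior_scale: float = 1.0,
    max_candidates: int | None = None,
) -> SelectionResult:
    """Greedy forward selection with blocked CV and Akaike weights.

    ``blocks`` defaults to the seasons present in the rankings (>= 2
    required).  At each step every unused candidate is appended to the
    incumbent set, scored by leave-one-block-out mean deviance, and
    weighted jointly with the incumbent; the best candidate is added only
    on strict weight improvement.
    """
    if blocks is None:
        blocks = r.seasons()
    if len(blocks) < 2:
        raise ValueError("blocked cross-validation needs at least 2 season blocks")
    candidates = sorted(str(c) for c in candidates)

    common = dict(
        alpha=alpha, min_size=min_size, kinship=kinship,
        prior_scale=prior_scale, max_candidates=max_candidates,
    )
    incumbent = _cv_candidate(r, cov, blocks, (), **common)
    incumbent.step = 0
    incumbent.accepted = True
    trail: list[CVResult] = [incumbent]
    selected: tuple[str, ...] = ()
    step = 0
    remaining = list(candidates)
    while remaining:
        step += 1
        cands = [
            _cv_candidate(r, cov, blocks, selected + (c,), **common) for c in remaining
        ]
        pool = [incumbent] + cands
        w = akaike_weights([c.mean_deviance for c in pool], [c.penalty for c in pool])
        for cv, wt in zip(pool, w):
            cv.akaike_weight = float(wt)
        for cv in cands:
            cv.step = step
            trail.append(cv)
        best_i = max(
            range(len(cands)),
            key=lambda i: (cands[i].akaike_weight, ),
        )
        # ties in weight resolved by (sorted) candidate name order: the
        # first maximal candidate wins because max() keeps the earliest
        best = cands[best_i]
        if best.akaike_weight > incumbent.akaike_weight:
            best.accepted = True
            selected = best.covariates
            remaining = [c for c in remaining if c != best.covariates[-1]]
            incumbent = best
        else:
            break
    return SelectionResult(selected=selected, trail=trail)
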