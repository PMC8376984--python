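"""Prediction-accuracy metrics for decentralized trials.

Accuracy is Kendall's tau between a predicted ordering (worths or
scores) and the observed farmer ranking, computed per field, averaged
within season, and combined across seasons with square-root-of-sample-
size weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plackett_luce import WorthVector
from .rankings import RankingSet

__all__ = [
    "PredictionAccuracy",
    "kendall_tau",
    "mean_field_tau",
    "combine_weighted",
    "comparison_table",
]


def _as_ordering(predicted, items: Sequence[str] | None = None) -> tuple[str, ...]:
    """Normalize a prediction (ordering, mapping item->score, Series or
    WorthVector) to a best-first ordering; score ties break
    lexicographically by item id."""
    if isinstance(predicted, WorthVector):
        return predicted.ordering()
    if isinstance(predicted, pd.Series):
        predicted = predicted.to_dict()
    if isinstance(predicted, Mapping):
        keys = list(predicted) if items is None else [i for i in items if i in predicted]
        return tuple(sorted(keys, key=lambda it: (-float(predicted[it]), it)))
    return tuple(predicted)


def kendall_tau(predicted, observed: Sequence[str]) -> float:
    """Kendall's tau-a between a predicted and an observed ordering.

    tau = (concordant - discordant) / (m(m-1)/2) over all pairs of the
    observed items; ``predicted`` may be an ordering or per-item scores
    (converted to an ordering first).
    """
    obs = tuple(observed)
    pred = _as_ordering(predicted, items=obs)
    common = [it for it in obs if it in pred]
    if len(common) < 2:
        raise ValueError("need at least 2 common items for Kendall tau")
    pred_rank = {it: i for i, it in enumerate(pred)}
    obs_rank = {it: i for i, it in enumerate(obs)}
    conc = disc = 0
    m = len(common)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = common[i], common[j]
            s = (pred_rank[a] - pred_rank[b]) * (obs_rank[a] - obs_rank[b])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    return (conc - disc) / (m * (m - 1) / 2)


def mean_field_tau(
    predictions: Mapping[str, object] | pd.Series | WorthVector,
    observed: RankingSet,
) -> dict[str, tuple[float, int]]:
    """Per-season mean field-level Kendall tau.

    ``predictions`` is either one global prediction (scores/worths applied
    to every field) or a mapping field_id -> prediction.  Returns
    {season: (mean tau, n fields)}.
    """
    per_field = False
    if isinstance(predictions, Mapping) and not isinstance(predictions, pd.Series):
        # per-field mappings have predictions (not bare scores) as values
        first = next(iter(predictions.values()), None)
        per_field = isinstance(first, (Mapping, pd.Series, WorthVector, tuple, list))
    taus: dict[str, list[float]] = {}
    missing = []
    for rec in observed.records:
        if per_field:
            if rec.group not in predictions:
                missing.append(rec.group)
                continue
            pred = predictions[rec.group]
        else:
            pred = predictions
        season = rec.season if rec.season is not None else "all"
        taus.setdefault(season, []).append(kendall_tau(pred, rec.ordering))
    if missing:
        raise KeyError(f"no prediction for fields: {missing[:10]}")
    return {s: (float(np.mean(v)), len(v)) for s, v in sorted(taus.items())}


def combine_weighted(taus: Sequence[float], ns: Sequence[int]) -> float:
    """Combine per-season tau values with sqrt(sample size) weights:
    sum(sqrt(n_s) tau_s) / sum(sqrt(n_s))."""
    taus = np.asarray(taus, float)
    ns = np.asarray(ns, float)
    if taus.size == 0 or taus.size != ns.size:
        raise ValueError("taus and ns must be equal-length and non-empty")
    if (ns <= 0).any():
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(ns)
    return float(np.sum(w * taus) / np.sum(w))


@dataclass
class PredictionAccuracy:
    """Per-season and combined accuracy for one method and trait."""

    method: str
    trait: str
    season_taus: dict[str, tuple[float, int]]

    @property
    def combined(self) -> float:
        taus = [t for t, _ in self.season_taus.values()]
        ns = [n for _, n in self.season_taus.values()]
        return combine_weighted(taus, ns)

    @classmethod
    def from_predictions(
        cls, method: str, trait: str, predictions, observed: RankingSet
    ) -> "PredictionAccuracy":
        return cls(method=method, trait=trait, season_taus=mean_field_tau(predictions, observed))


def comparison_table(
    benchmark_acc: Sequence[PredictionAccuracy],
    tdb_acc: Sequence[PredictionAccuracy],
) -> pd.DataFrame:
    """Table-style comparison: one row per method x trait x season plus
    the sqrt(n)-weighted combined row per method x trait."""
    all_acc = list(benchmark_acc) + list(tdb_acc)
    seasons_by_trait: dict[str, set] = {}
    for acc in all_acc:
        seasons_by_trait.setdefault(acc.trait, set()).update(acc.season_taus)
    for trait, seasons in seasons_by_trait.items():
        for acc in all_acc:
            if acc.trait == trait and set(acc.season_taus) != seasons:
                raise ValueError(
                    f"season mismatch for trait {trait!r}: "
                    f"{sorted(acc.season_taus)} vs {sorted(seasons)}"
                )
    rows = []
    for acc in all_acc:
        for season, (tau, n) in acc.season_taus.items():
            rows.append(
                {"method": acc.method, "trait": acc.trait, "season": season,
                 "n": n, "tau": tau}
            )
        rows.append(
            {"method": acc.method, "trait": acc.trait, "season": "combined",
             "n": sum(n for _, n in acc.season_taus.values()), "tau": acc.combined}
        )
    return pd.DataFrame(rows, columns=["method", "trait", "season", "n", "tau"])
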