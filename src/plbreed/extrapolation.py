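"""Scenario extrapolation of a fitted Plackett-Luce tree.

Applies a tree across simulated seasonal scenarios (historical seasons x
representative sowing dates at a set of target points), averages per-
point win probabilities, and summarizes the top-k recommendation against
a check variety: win probability (normalized worth), reliability
P(i beats check) = alpha_i / (alpha_i + alpha_check), and the expected
percentage grain-yield gain under a linked yield model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import DailyWeather, PhaseWindows, compute_indices
from .plackett_luce import WorthVector
from .pltree import PLTree
from .synthetic_data import TrueModel

__all__ = [
    "win_probability",
    "reliability",
    "simulate_scenarios",
    "top_k_vs_check",
]


def win_probability(w: WorthVector) -> pd.Series:
    """P(item wins against all others) = normalized worth (the sum-to-one
    gauge makes the win probability equal alpha itself)."""
    return pd.Series(w.worths / w.worths.sum(), index=list(w.items), name="win_probability")


def reliability(w: WorthVector, item: str, check: str) -> float:
    """P(item beats check) = alpha_i / (alpha_i + alpha_check)."""
    for x in (item, check):
        if x not in w.items:
            raise KeyError(f"unknown item {x!r}")
    ai, aj = w[item], w[check]
    return ai / (ai + aj)


def simulate_scenarios(
    tree: PLTree,
    weather: Mapping[str, DailyWeather],
    seasons: Sequence[int],
    sowing_dates: Sequence[tuple[int, int]],
    phase_durations: Sequence[int] = (60, 95, 120),
    exclude_seasons: Sequence[int] = (),
    index_set: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict tree worths across points x seasons x sowing dates.

    ``weather`` maps point ids to multi-year daily series; ``seasons``
    are calendar years; ``sowing_dates`` are (month, day) tuples (e.g.
    the midpoints of equiprobable planting-date quantile intervals).
    Phase windows are built from each sowing date with fixed phase
    durations.  Seasons in ``exclude_seasons`` (e.g. those used as test
    data) are dropped, so each point yields
    (len(seasons) - len(excluded)) * len(sowing_dates) scenario rows.

    Returns (scenario table, per-point averaged win probabilities); the
    averaged probabilities per point sum to one across genotypes.
    """
    needed = tree.split_covariates()
    base_indices = sorted({n.rsplit("_", 1)[0] for n in needed}) if needed else None
    indices = tuple(index_set) if index_set is not None else (
        tuple(base_indices) if base_indices else ("minNT",)
    )
    use_seasons = [s for s in seasons if s not in set(exclude_seasons)]
    rows = []
    avg: dict[str, pd.Series] = {}
    for point, wx in weather.items():
        probs = []
        for year in use_seasons:
            for month, day in sowing_dates:
                sowing = pd.Timestamp(year=int(year), month=month, day=day)
                pw = PhaseWindows.from_durations(sowing, phase_durations)
                cov_row = compute_indices(wx, pw, index_set=indices)
                leaf = tree.route(cov_row)
                p = win_probability(leaf.fit.worths)
                probs.append(p)
                for item, prob in p.items():
                    rows.append(
                        {
                            "point_id": point,
                            "season": int(year),
                            "sowing_date": sowing.date().isoformat(),
                            "leaf_id": leaf.node_id,
                            "item": item,
                            "win_probability": float(prob),
                        }
                    )
        mean = pd.concat(probs, axis=1).mean(axis=1)
        avg[point] = mean / mean.sum()
    scenario_table = pd.DataFrame(rows)
    averaged = pd.DataFrame(avg).T.rename_axis("point_id")
    return scenario_table, averaged


def top_k_vs_check(
    averaged_worths: pd.DataFrame,
    check: str,
    k: int = 3,
    yield_model: TrueModel | None = None,
    above_threshold: Mapping[str, bool] | bool = False,
) -> pd.DataFrame:
    """Per-point top-k recommendation versus the check variety.

    For each point the k genotypes with the largest averaged worth are
    selected (the check is never recommended against itself: reliability
    versus itself is excluded).  Reliability of each vs the check follows
    the pairwise worth ratio.  When a yield model is supplied the
    expected percentage yield gain of the selection is computed from the
    model's predicted grain yields under the point's switch condition
    (synthetic runs; on real data this output is descriptive only).
    """
    if check not in averaged_worths.columns:
        raise KeyError(f"check {check!r} not among items")
    if k >= averaged_worths.shape[1]:
        raise ValueError("k must be smaller than the number of items")
    out = []
    for point, row in averaged_worths.iterrows():
        ranked = row.drop(labels=[check]).sort_values(ascending=False)
        top = list(ranked.index[:k])
        rels = [float(row[t] / (row[t] + row[check])) for t in top]
        rec: dict[str, object] = {
            "point_id": point,
            "top_items": ",".join(top),
            "mean_reliability": float(np.mean(rels)),
            "min_reliability": float(np.min(rels)),
        }
        for i, (t, rl) in enumerate(zip(top, rels), start=1):
            rec[f"top{i}"] = t
            rec[f"reliability_top{i}"] = rl
        if yield_model is not None:
            above = (
                bool(above_threshold[point])
                if isinstance(above_threshold, Mapping)
                else bool(above_threshold)
            )
            lw = yield_model.log_worths(above)
            lw = lw - lw.mean()
            gy = yield_model.yield_base + yield_model.yield_scale * lw
            gy_s = pd.Series(gy, index=list(yield_model.items))
            gain = (gy_s[top].mean() - gy_s[check]) / gy_s[check] * 100.0
            rec["yield_gain_pct"] = float(gain)
        out.append(rec)
    return pd.DataFrame(out).set_index("point_id")
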