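"""Grouped-ranking data model and I/O.

Decentralized (tricot) trials produce one ranking of a small genotype
subset per farmer field.  This module houses the container for those
rankings, construction of rankings from per-plot measurements (e.g. grain
yield), the pairwise win/loss comparison graph, and the connectivity check
that determines whether a plain Plackett-Luce maximum-likelihood fit is
identifiable.

Conventions: rank 1 is best; orderings are stored best-first; ties in
measured values are broken by item-id lexicographic order and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Ranking",
    "RankingSet",
    "SchemaError",
    "rank_from_measures",
    "comparison_graph",
    "check_connectivity",
    "read_rankings",
    "write_rankings",
]


class SchemaError(ValueError):
    """Raised when a rankings file violates the documented schema."""


@dataclass(frozen=True)
class Ranking:
    """One observed ordering: a group key (field), a best-first ordering,
    an optional season label, a positive weight and a tie flag."""

    group: str
    ordering: tuple[str, ...]
    season: str | None = None
    weight: float = 1.0
    tied: bool = False

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            raise ValueError(f"duplicate item in ordering for group {self.group!r}")
        if not self.weight > 0:
            raise ValueError("ranking weight must be > 0")


class RankingSet:
    """A collection of grouped orderings over a common item universe."""

    def __init__(self, records: Iterable[Ranking], items: Sequence[str] | None = None):
        self.records: list[Ranking] = list(records)
        observed: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            for it in rec.ordering:
                if it not in seen:
                    seen.add(it)
                    observed.append(it)
        if items is None:
            self.items: tuple[str, ...] = tuple(sorted(observed))
        else:
            self.items = tuple(items)
            unknown = seen - set(self.items)
            if unknown:
                raise ValueError(f"orderings contain unknown items: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RankingSet)
            and self.items == other.items
            and self.records == other.records
        )

    def seasons(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.season is not None and rec.season not in out:
                out.append(rec.season)
        return out

    def subset(self, predicate: Callable[[Ranking], bool]) -> "RankingSet":
        return RankingSet([r for r in self.records if predicate(r)], items=self.items)

    def by_season(self, season: str) -> "RankingSet":
        return self.subset(lambda r: r.season == season)

    def select(self, indices: Sequence[int]) -> "RankingSet":
        return RankingSet([self.records[i] for i in indices], items=self.items)

    def ranked_items(self) -> tuple[str, ...]:
        """Items that actually appear in at least one ordering."""
        seen: set[str] = set()
        for rec in self.records:
            seen.update(rec.ordering)
        return tuple(s for s in self.items if s in seen)

    def to_arrays(self, items: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Dense integer representation for fitting.

        Returns (orderings, weights): orderings is (n_records, max_len),
        item indices best-first padded with -1; weights is (n_records,).
        """
        items = self.items if items is None else tuple(items)
        index = {it: i for i, it in enumerate(items)}
        max_len = max((len(r.ordering) for r in self.records), default=0)
        orderings = np.full((len(self.records), max_len), -1, dtype=np.int64)
        weights = np.empty(len(self.records))
        for i, rec in enumerate(self.records):
            for j, it in enumerate(rec.ordering):
                orderings[i, j] = index[it]
            weights[i] = rec.weight
        return orderings, weights


def rank_from_measures(
    plot_values: pd.DataFrame | Mapping[str, Mapping[str, float]],
    direction: str = "higher_is_better",
    *,
    seasons: Mapping[str, str] | None = None,
) -> RankingSet:
    """Build a RankingSet from per-plot measurements.

    ``plot_values`` is either a long DataFrame with columns
    (group, item, value[, season]) or a mapping group -> {item: value}.
    ``direction`` is ``higher_is_better`` (e.g. grain yield) or
    ``lower_is_better``.  Exact ties are broken by item id (lexicographic)
    and the record is flagged ``tied=True``.
    """
    if direction not in ("higher_is_better", "lower_is_better"):
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(plot_values, pd.DataFrame):
        df = plot_values
        groups: dict[str, dict[str, float]] = {}
        season_map: dict[str, str] = {} if seasons is None else dict(seasons)
        for _, row in df.iterrows():
            g = str(row["group"])
            groups.setdefault(g, {})[str(row["item"])] = float(row["value"])
            if "season" in df.columns and g not in season_map:
                season_map[g] = str(row["season"])
    else:
        groups = {g: dict(v) for g, v in plot_values.items()}
        season_map = {} if seasons is None else dict(seasons)

    records = []
    for g in groups:
        vals = groups[g]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 items")
        for it, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"non-numeric measurement for item {it!r} in group {g!r}")
        sign = -1.0 if direction == "higher_is_better" else 1.0
        ordered = sorted(vals, key=lambda it: (sign * vals[it], it))
        n_unique = len(set(vals.values()))
        records.append(
            Ranking(
                group=g,
                ordering=tuple(ordered),
                season=season_map.get(g),
                tied=n_unique < len(vals),
            )
        )
    return RankingSet(records)


def comparison_graph(r: RankingSet) -> nx.DiGraph:
    """Directed win graph: edge (winner, loser, wins=count) obtained by
    pairwise expansion of every ordering (a full ordering of m items
    contributes m(m-1)/2 ordered pairs)."""
    g = nx.DiGraph()
    g.add_nodes_from(r.ranked_items())
    for rec in r.records:
        o = rec.ordering
        for i in range(len(o)):
            for j in range(i + 1, len(o)):
                if g.has_edge(o[i], o[j]):
                    g[o[i]][o[j]]["wins"] += 1
                else:
                    g.add_edge(o[i], o[j], wins=1)
    return g


def check_connectivity(r: RankingSet) -> tuple[dict[str, int], bool]:
    """Component labels of the win/loss digraph and a strong-connectivity
    flag.  A strongly connected graph is the existence condition for the
    Plackett-Luce maximum-likelihood estimate."""
    if len(r) == 0:
        raise ValueError("empty RankingSet")
    g = comparison_graph(r)
    comps = list(nx.strongly_connected_components(g))
    labels: dict[str, int] = {}
    for lab, comp in enumerate(sorted(comps, key=lambda c: sorted(c)[0])):
        for item in comp:
            labels[item] = lab
    return labels, len(comps) == 1


# ---------------------------------------------------------------------------
# CSV I/O.  Long format: field_id, season, item, rank.  Wide format:
# field_id, season, item_1..item_k, rank_1..rank_k.  UTF-8, header required.
# ---------------------------------------------------------------------------

def write_rankings(r: RankingSet, path, dialect: str = "long") -> None:
    if dialect == "long":
        rows = [
            {"field_id": rec.group, "season": rec.season, "item": it, "rank": k + 1}
            for rec in r.records
            for k, it in enumerate(rec.ordering)
        ]
        pd.DataFrame(rows, columns=["field_id", "season", "item", "rank"]).to_csv(
            path, index=False
        )
    elif dialect == "wide":
        width = max((len(rec.ordering) for rec in r.records), default=0)
        rows = []
        for rec in r.records:
            row: dict[str, object] = {"field_id": rec.group, "season": rec.season}
            for k, it in enumerate(rec.ordering):
                row[f"item_{k + 1}"] = it
                row[f"rank_{k + 1}"] = k + 1
            rows.append(row)
        cols = ["field_id", "season"]
        cols += [f"item_{k + 1}" for k in range(width)]
        cols += [f"rank_{k + 1}" for k in range(width)]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_rankings(path, dialect: str = "long") -> RankingSet:
    df = pd.read_csv(path, dtype={"field_id": str})
    if dialect == "long":
        required = {"field_id", "season", "item", "rank"}
        if not required.issubset(df.columns):
            raise SchemaError(f"long rankings file must have columns {sorted(required)}")
        records = []
        for (g,), sub in df.groupby(["field_id"], sort=True):
            sub = sub.sort_values("rank")
            ranks = sub["rank"].to_numpy()
            if not np.array_equal(ranks, np.arange(1, len(sub) + 1)):
                row = int(sub.index[0]) + 2  # 1-based + header
                raise SchemaError(f"rank gaps or duplicates for field {g!r} near row {row}")
            items = [str(x) for x in sub["item"]]
            if len(set(items)) != len(items):
                row = int(sub.index[0]) + 2
                raise SchemaError(f"duplicate item within field {g!r} near row {row}")
            season = sub["season"].iloc[0]
            records.append(
                Ranking(group=str(g), ordering=tuple(items),
                        season=None if pd.isna(season) else str(season))
            )
        return RankingSet(records)
    if dialect == "wide":
        item_cols = sorted(
            (c for c in df.columns if c.startswith("item_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if "field_id" not in df.columns or not item_cols:
            raise SchemaError("wide rankings file must have field_id and item_k columns")
        records = []
        for idx, row in df.iterrows():
            pairs = []
            for c in item_cols:
                if pd.isna(row[c]):
                    continue
                k = int(c.split("_")[1])
                rank_col = f"rank_{k}"
                rank = k if rank_col not in df.columns or pd.isna(row[rank_col]) else int(row[rank_col])
                pairs.append((rank, str(row[c])))
            pairs.sort()
            items = [it for _, it in pairs]
            if len(set(items)) != len(items):
                raise SchemaError(f"duplicate item within field {row['field_id']!r} at row {int(idx) + 2}")
            if [rk for rk, _ in pairs] != list(range(1, len(pairs) + 1)):
                raise SchemaError(f"rank gaps for field {row['field_id']!r} at row {int(idx) + 2}")
            season = row.get("season")
            records.append(
                Ranking(group=str(row["field_id"]), ordering=tuple(items),
                        season=None if pd.isna(season) else str(season))
            )
        return RankingSet(records)
    raise ValueError(f"unknown dialect {dialect!r}")
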