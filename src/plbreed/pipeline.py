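"""End-to-end orchestration of the synthetic comparison experiment.

Generates a scenario, runs the centralized genomic-prediction benchmark
(station BLUPs -> GBLUP -> farm predictions) and the decentralized
pipeline (covariate forward selection -> Plackett-Luce tree -> per-season
holdout predictions), scores both with field-level Kendall tau, and
emits the comparison report plus scenario extrapolation outputs.

Everything is driven by a :class:`PipelineConfig` with explicit seeds;
two runs with equal configs produce identical outputs.
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import (
    clean_markers,
    fit_gblup,
    kinship_vanraden,
    predict_gblup,
    station_blup,
    station_oa_means,
)
from .evaluation import PredictionAccuracy, comparison_table, kendall_tau, mean_field_tau
from .extrapolation import simulate_scenarios, top_k_vs_check
from .model_selection import SelectionResult, forward_select
from .pltree import PLTree, grow_tree
from .rankings import RankingSet
from .synthetic_data import (
    Scenario,
    ScenarioConfig,
    gen_multiyear_weather,
    generate_scenario,
    write_scenario,
)

__all__ = [
    "PipelineConfig",
    "ThreeDBResult",
    "run_benchmark",
    "run_3db",
    "run_report",
    "compare_methods",
    "benchmark_station_next_season",
    "stratified_accuracy",
]


@dataclass
class PipelineConfig:
    """Scenario generation plus analysis settings in one place."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    candidates: tuple[str, ...] = ("minNT_veg", "maxNT_rep", "meanDT_veg", "rain_full")
    alpha: float = 0.01
    min_size: float = 0.20
    prior_scale: float = 1.0
    use_kinship: bool = True
    max_candidates: int | None = 16
    training_fraction: float = 1.0
    benchmark_train_subset: str = "all"  # all | farm | disjoint
    n_points: int = 12
    scenario_start_year: int = 2001
    n_scenario_seasons: int = 15
    n_sowing_dates: int = 3
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"scenario": asdict(self.scenario),
                 "analysis": {k: v for k, v in asdict(self).items() if k != "scenario"}},
                fh, sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sc_raw = raw.get("scenario", {})
        for key in ("season_sizes", "station_seasons", "phase_durations", "n_raters",
                    "climate_indices"):
            if key in sc_raw and sc_raw[key] is not None:
                sc_raw[key] = tuple(sc_raw[key])
        analysis = raw.get("analysis", {})
        if "candidates" in analysis and analysis["candidates"] is not None:
            analysis["candidates"] = tuple(analysis["candidates"])
        return cls(scenario=ScenarioConfig(**sc_raw), **analysis)


@dataclass
class ThreeDBResult:
    accuracy: PredictionAccuracy
    tree: PLTree
    selection: SelectionResult


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

def _station_phenotypes(scenario: Scenario) -> dict[str, pd.Series]:
    """Per-genotype station BLUPs for GY and rater-pooled OA."""
    gy_blups, _ = station_blup(scenario.station_plots, trait="gy")
    oa_means = station_oa_means(scenario.station_oa)
    meta = scenario.station_plots[["plot_id", "replicate", "block"]]
    oa_plot = oa_means.merge(meta, on="plot_id", how="left")
    oa_blups, _ = station_blup(oa_plot, trait="oa_mean")
    return {"GY": gy_blups, "OA": oa_blups}


def run_benchmark(
    scenario: Scenario, config: PipelineConfig
) -> list[PredictionAccuracy]:
    """Centralized benchmark: station BLUPs feed a GBLUP trained on the
    station population and predict the on-farm test genotypes; accuracy
    is the per-season field-level Kendall tau against farm rankings.

    ``config.benchmark_train_subset`` selects the training population:
    the whole station set (default), the 41-equivalent on-farm subset
    (``farm``), or the station set excluding the on-farm genotypes
    (``disjoint``, no train/test overlap).
    """
    K = kinship_vanraden(clean_markers(scenario.markers))
    phen = _station_phenotypes(scenario)
    farm = list(scenario.farm_items) + [scenario.check]
    out = []
    observed = {"OA": scenario.oa_rankings, "GY": scenario.gy_rankings}
    for trait, y in phen.items():
        if config.benchmark_train_subset == "farm":
            y = y.loc[[g for g in y.index if g in set(farm)]]
        elif config.benchmark_train_subset == "disjoint":
            y = y.loc[[g for g in y.index if g not in set(farm)]]
        elif config.benchmark_train_subset != "all":
            raise ValueError(f"unknown benchmark_train_subset {config.benchmark_train_subset!r}")
        model = fit_gblup(y, K)
        preds = predict_gblup(model, farm, K)
        out.append(
            PredictionAccuracy.from_predictions("benchmark", trait, preds, observed[trait])
        )
    return out


def benchmark_station_next_season(scenario: Scenario) -> float:
    """First benchmark scenario: train on the first station season (all
    genotypes), predict the on-farm subset's GY BLUPs in the next station
    season; returns the Kendall tau between predicted and observed."""
    seasons = sorted(set(scenario.station_plots["season"]))
    if len(seasons) < 2:
        raise ValueError("need at least 2 station seasons")
    first, second = seasons[0], seasons[1]
    K = kinship_vanraden(clean_markers(scenario.markers))
    plots1 = scenario.station_plots[scenario.station_plots["season"] == first]
    plots2 = scenario.station_plots[scenario.station_plots["season"] == second]
    y1, _ = station_blup(plots1, trait="gy")
    y2, _ = station_blup(plots2, trait="gy")
    model = fit_gblup(y1, K)
    farm = [g for g in scenario.farm_items if g in y2.index]
    preds = predict_gblup(model, farm, K)
    observed_order = tuple(y2.loc[farm].sort_values(ascending=False).index)
    return kendall_tau(preds, observed_order)


def stratified_accuracy(
    predictions,
    observed: RankingSet,
    distance: pd.Series,
    n_strata: int = 3,
) -> pd.DataFrame:
    """Field-level tau stratified by environmental distance (e.g. the
    absolute difference between a field's covariate and the station mean),
    split into equal-count strata."""
    recs = [r for r in observed.records if r.group in distance.index]
    d = distance.loc[[r.group for r in recs]].to_numpy(float)
    qs = np.quantile(d, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(qs, d, side="right") - 1, 0, n_strata - 1)
    rows = []
    for s in range(n_strata):
        sub = [recs[i] for i in np.flatnonzero(strata == s)]
        if not sub:
            continue
        taus = [kendall_tau(predictions, r.ordering) for r in sub]
        rows.append(
            {"stratum": s + 1, "n": len(sub), "mean_distance": float(d[strata == s].mean()),
             "tau": float(np.mean(taus))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decentralized (3D-breeding style) pipeline
# ---------------------------------------------------------------------------

def _subsample(r: RankingSet, fraction: float, seed: int) -> RankingSet:
    if fraction >= 1.0:
        return r
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    by_season: dict[str | None, list[int]] = {}
    for i, rec in enumerate(r.records):
        by_season.setdefault(rec.season, []).append(i)
    for season, idx in by_season.items():
        k = max(2, int(round(fraction * len(idx))))
        keep.extend(rng.choice(idx, size=min(k, len(idx)), replace=False).tolist())
    return r.select(sorted(keep))


def run_3db(
    scenario: Scenario,
    config: PipelineConfig,
    trait: str = "OA",
    training_fraction: float | None = None,
) -> ThreeDBResult:
    """Decentralized pipeline for one trait.

    Forward-selects covariates with seasons as CV blocks, then scores
    each season by holdout: a tree grown on the other seasons predicts
    worths for the held-out season's fields.  The returned tree is grown
    on all records with the selected covariates.
    """
    trait = trait.upper()
    rankings = {"OA": scenario.oa_rankings, "GY": scenario.gy_rankings}[trait]
    fraction = config.training_fraction if training_fraction is None else training_fraction
    rankings = _subsample(rankings, fraction, seed=config.seed)
    cov = scenario.covariates
    kinship = None
    if config.use_kinship:
        farm = list(scenario.farm_items) + [scenario.check]
        K = kinship_vanraden(clean_markers(scenario.markers))
        kinship = K.loc[farm, farm]
    candidates = [c for c in config.candidates if c in cov.columns]
    selection = forward_select(
        rankings, cov, candidates,
        alpha=config.alpha, min_size=config.min_size,
        kinship=kinship, prior_scale=config.prior_scale,
        max_candidates=config.max_candidates,
    )
    selected = list(selection.selected)
    season_taus: dict[str, tuple[float, int]] = {}
    for season in rankings.seasons():
        train = rankings.subset(lambda rec: rec.season != season)
        test = rankings.subset(lambda rec: rec.season == season)
        tree_s = grow_tree(
            train, cov, covariates=selected,
            alpha=config.alpha, min_size=config.min_size,
            kinship=kinship, prior_scale=config.prior_scale,
            max_candidates=config.max_candidates,
        )
        preds = {rec.group: tree_s.route(cov.loc[rec.group]).fit.worths for rec in test}
        season_taus.update(mean_field_tau(preds, test))
    tree = grow_tree(
        rankings, cov, covariates=selected,
        alpha=config.alpha, min_size=config.min_size,
        kinship=kinship, prior_scale=config.prior_scale,
        max_candidates=config.max_candidates,
    )
    acc = PredictionAccuracy(method="3d-breeding", trait=trait, season_taus=season_taus)
    return ThreeDBResult(accuracy=acc, tree=tree, selection=selection)


# ---------------------------------------------------------------------------
# Whole experiment
# ---------------------------------------------------------------------------

def compare_methods(
    config: PipelineConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate one scenario and score benchmark vs decentralized for both
    traits.  Returns (comparison table, details with fitted objects)."""
    config = config or PipelineConfig()
    if seed is not None:
        config.seed = seed
    scenario = generate_scenario(config.scenario, seed=config.seed)
    bench = run_benchmark(scenario, config)
    tdb_oa = run_3db(scenario, config, trait="OA")
    tdb_gy = run_3db(scenario, config, trait="GY")
    table = comparison_table(bench, [tdb_oa.accuracy, tdb_gy.accuracy])
    return table, {
        "scenario": scenario,
        "benchmark": bench,
        "3db": {"OA": tdb_oa, "GY": tdb_gy},
    }


def run_report(config: PipelineConfig | None = None, outdir: str = "report", seed: int | None = None) -> dict:
    """Run the full experiment and write every documented artifact:
    scenario CSVs, the comparison table, the selection trail, the
    serialized tree, scenario/reliability CSVs and a run log."""
    config = config or PipelineConfig()
    if seed is not None:
        config.seed = seed
    os.makedirs(outdir, exist_ok=True)
    table, details = compare_methods(config)
    scenario: Scenario = details["scenario"]

    written = write_scenario(scenario, os.path.join(outdir, "data"))
    table.to_csv(os.path.join(outdir, "comparison_table.csv"), index=False)
    tdb_oa: ThreeDBResult = details["3db"]["OA"]
    tdb_oa.selection.trail_frame().to_csv(
        os.path.join(outdir, "selection_trail_oa.csv"), index=False
    )
    with open(os.path.join(outdir, "pltree_oa.json"), "w") as fh:
        fh.write(tdb_oa.tree.to_json())

    # scenario extrapolation with the final OA tree
    weather, is_cold = gen_multiyear_weather(
        config.n_points,
        start_year=config.scenario_start_year,
        n_years=config.n_scenario_seasons,
        seed=config.seed + 101,
        cold_fraction=config.scenario.cold_fraction,
    )
    from .climate import sowing_windows

    sow = sowing_windows(
        list(scenario.env.farm_fields()["planting_date"]), k=config.n_sowing_dates
    )
    sowing_dates = [(d.month, d.day) for d in sow]
    seasons = list(range(config.scenario_start_year,
                         config.scenario_start_year + config.n_scenario_seasons))
    scen_table, averaged = simulate_scenarios(
        tdb_oa.tree, weather, seasons, sowing_dates,
        phase_durations=config.scenario.phase_durations,
    )
    scen_table.to_csv(os.path.join(outdir, "scenario_predictions.csv"), index=False)
    averaged.to_csv(os.path.join(outdir, "scenario_mean_win_probability.csv"))
    summary = top_k_vs_check(
        averaged, check=scenario.check, k=3,
        yield_model=scenario.model,
        above_threshold={p: not c for p, c in is_cold.items()},
    )
    summary.to_csv(os.path.join(outdir, "topk_vs_check.csv"))

    log = {
        "plbreed_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_farm_fields": int(len(scenario.design)),
        "n_farm_plots": int(len(scenario.farm_plots)),
        "n_station_plots": int(len(scenario.station_plots)),
        "n_station_plots_per_field": int(
            scenario.station_plots.groupby(["location", "season"]).size().iloc[0]
        ),
        "selected_covariates_oa": list(tdb_oa.selection.selected),
        "artifacts": sorted(
            written
            + [
                "comparison_table.csv", "selection_trail_oa.csv", "pltree_oa.json",
                "scenario_predictions.csv", "scenario_mean_win_probability.csv",
                "topk_vs_check.csv", "run_log.json",
            ]
        ),
    }
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)
    return {"table": table, "log": log, "details": details}
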