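"""Synthetic decentralized-trial scenarios with known ground truth.

Emulates the statistical structure of a decentralized (tricot) durum
wheat evaluation nested in a centralized station program: SNP markers for
a station population, a subset of genotypes distributed on farms as
incomplete blocks of three test entries plus a check, daily weather per
site with a configurable fraction of farm sites colder than every
station, latent Plackett-Luce worths with a single covariate-dependent
switch (genotype-by-environment interaction as a night-temperature
threshold), farmer rankings drawn from those worths, per-plot grain
yields linked to log-worth, and a replicated station trial with grain
yield and 1-5 overall-appreciation scores by rater gender.

All generators take explicit integer seeds; no global random state is
used.  Generator defaults are free parameters of the scenario (they are
not estimates of any real dataset) and are documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .climate import DailyWeather, PhaseWindows, compute_covariate_table
from .rankings import Ranking, RankingSet, rank_from_measures, write_rankings

__all__ = [
    "TrueModel",
    "Environment",
    "ScenarioConfig",
    "Scenario",
    "gen_markers",
    "gen_true_model",
    "gen_environment",
    "gen_true_worths",
    "gen_tricot_design",
    "gen_tricot_trial",
    "gen_station_design",
    "gen_station_trial",
    "generate_scenario",
    "write_scenario",
]


@dataclass(frozen=True)
class TrueModel:
    """Latent data-generating model for genotype worths and yields.

    ``log_worth_base`` is the additive genetic value (built from markers);
    ``log_worth_shift`` is added when the switch covariate *strictly
    exceeds* the threshold (a field exactly at the threshold takes base
    worths).  Grain yield is linked to centred log-worth:
    GY = yield_base + yield_scale * centred log-worth + N(0, noise_sd),
    truncated at zero.
    """

    items: tuple[str, ...]
    log_worth_base: np.ndarray
    switch_covariate: str
    switch_threshold: float
    log_worth_shift: np.ndarray
    yield_scale: float
    noise_sd: float
    yield_base: float = 2.5

    def __post_init__(self) -> None:
        base = np.asarray(self.log_worth_base, dtype=float)
        shift = np.asarray(self.log_worth_shift, dtype=float)
        object.__setattr__(self, "log_worth_base", base)
        object.__setattr__(self, "log_worth_shift", shift)
        if not (len(self.items) == base.size == shift.size):
            raise ValueError("items, base and shift must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.yield_scale <= 0:
            raise ValueError("yield_scale must be > 0")

    def log_worths(self, above_threshold: bool) -> np.ndarray:
        return self.log_worth_base + (self.log_worth_shift if above_threshold else 0.0)


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def gen_markers(
    n_genotypes: int,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Biallelic SNP dosages in {0,1,2} at Hardy-Weinberg proportions.

    Each SNP draws a minor-allele frequency uniformly in
    [maf_low, maf_high]; dosages are Binomial(2, maf) per genotype.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if n_genotypes < 2 or n_snps < 2:
        raise ValueError("need at least 2 genotypes and 2 SNPs")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    dosages = rng.binomial(2, maf[None, :], size=(n_genotypes, n_snps)).astype(np.int8)
    if ids is None:
        ids = [f"G{i + 1:03d}" for i in range(n_genotypes)]
    cols = [f"SNP{j + 1:04d}" for j in range(n_snps)]
    df = pd.DataFrame(dosages, index=list(ids), columns=cols)
    df.attrs["maf"] = maf
    return df


def gen_true_model(
    markers: pd.DataFrame,
    seed: int = 0,
    base_sd: float = 0.75,
    shift_sd: float = 1.5,
    switch_covariate: str = "minNT_veg",
    switch_threshold: float = 11.5,
    yield_scale: float = 0.35,
    yield_base: float = 2.5,
    noise_sd: float = 0.4,
) -> TrueModel:
    """Marker-derived TrueModel: base and shift log-worths are linear in
    centred dosages (u = W beta) and rescaled to the requested standard
    deviations, so both the main effect and the G-by-E switch have an
    additive genetic basis that a kinship matrix can capture."""
    rng = np.random.default_rng(seed)
    Z = markers.to_numpy(float)
    Z = Z - Z.mean(axis=0, keepdims=True)

    def effect(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(Z.shape[0])
        beta = rng.normal(size=Z.shape[1])
        u = Z @ beta
        s = u.std()
        u = u / s * sd if s > 0 else u
        return u - u.mean()

    return TrueModel(
        items=tuple(markers.index),
        log_worth_base=effect(base_sd),
        switch_covariate=switch_covariate,
        switch_threshold=switch_threshold,
        log_worth_shift=effect(shift_sd),
        yield_scale=yield_scale,
        noise_sd=noise_sd,
        yield_base=yield_base,
    )


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

@dataclass
class Environment:
    """Generated sites: a table of farm fields and stations plus the daily
    weather series and growth-phase windows for each site."""

    sites: pd.DataFrame
    weather: dict[str, DailyWeather]
    phases: dict[str, PhaseWindows]

    def farm_fields(self) -> pd.DataFrame:
        return self.sites[self.sites["kind"] == "farm"].reset_index(drop=True)

    def stations(self) -> pd.DataFrame:
        return self.sites[self.sites["kind"] == "station"].reset_index(drop=True)


def _daily_series(
    rng: np.random.Generator,
    site_id: str,
    level: float,
    start: pd.Timestamp,
    end: pd.Timestamp,
    daily_sd: float = 0.6,
    seasonal_amp: float = 1.5,
) -> DailyWeather:
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    tmin = level + seasonal_amp * np.sin(2 * np.pi * (doy - 120) / 365.0) + rng.normal(
        0, daily_sd, size=len(dates)
    )
    gap = 6.0 + np.abs(rng.normal(0, 1.5, size=len(dates)))
    tmax = tmin + gap
    wet = rng.random(len(dates)) < 0.35
    precip = np.where(wet, rng.gamma(1.2, 5.0, size=len(dates)), 0.0)
    return DailyWeather(
        site_id=site_id,
        data=pd.DataFrame(
            {"date": dates, "tmin": tmin, "tmax": tmax, "precip": np.round(precip, 2)}
        ),
    )


def gen_environment(
    n_fields: int,
    n_seasons: int = 3,
    n_stations: int = 2,
    seed: int = 0,
    cold_fraction: float = 0.3,
    season_sizes: Sequence[int] | None = None,
    phase_durations: Sequence[int] = (60, 95, 120),
    start_year: int = 2013,
    planting_jitter_days: int = 12,
    station_level: float = 16.0,
    warm_level: float = 16.5,
    cold_level: float = 10.5,
) -> Environment:
    """Farm-field sites over seasons plus station sites, with weather.

    Exactly ``round(cold_fraction * n_fields)`` farm sites are drawn cold
    (site temperature level well below every station); the remaining farm
    sites sit slightly above station level.  Every day satisfies
    tmin <= tmax and each site's series covers its growing window.
    """
    if n_fields < 1 or n_seasons < 1 or n_stations < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    if season_sizes is None:
        base = n_fields // n_seasons
        season_sizes = [base] * n_seasons
        for i in range(n_fields - base * n_seasons):
            season_sizes[i] += 1
    elif len(season_sizes) != n_seasons or sum(season_sizes) != n_fields:
        raise ValueError("season_sizes must have n_seasons entries summing to n_fields")

    n_cold = int(round(cold_fraction * n_fields))
    cold_idx = set(rng.choice(n_fields, size=n_cold, replace=False).tolist())

    rows = []
    weather: dict[str, DailyWeather] = {}
    phases: dict[str, PhaseWindows] = {}
    fid = 0
    for s, size in enumerate(season_sizes):
        season = f"S{s + 1}"
        base_planting = pd.Timestamp(year=start_year + s, month=7, day=1)
        for _ in range(size):
            fid += 1
            field_id = f"F{fid:04d}"
            is_cold = (fid - 1) in cold_idx
            level = (
                cold_level + rng.normal(0, 0.8)
                if is_cold
                else warm_level + rng.normal(0, 0.3)
            )
            planting = base_planting + pd.Timedelta(
                days=int(rng.integers(-planting_jitter_days, planting_jitter_days + 1))
            )
            pw = PhaseWindows.from_durations(planting, phase_durations)
            weather[field_id] = _daily_series(
                rng,
                field_id,
                level,
                planting - pd.Timedelta(days=5),
                pw.harvest_date + pd.Timedelta(days=5),
            )
            phases[field_id] = pw
            rows.append(
                {
                    "site_id": field_id,
                    "field_id": field_id,
                    "kind": "farm",
                    "season": season,
                    "planting_date": planting,
                    "level": level,
                    "is_cold": is_cold,
                }
            )
    for st in range(n_stations):
        site_id = f"ST{st + 1}"
        level = station_level + rng.normal(0, 0.1)
        planting = pd.Timestamp(year=start_year - 1, month=7, day=1)
        pw = PhaseWindows.from_durations(planting, phase_durations)
        # station weather spans all study seasons for reuse across years
        end = pd.Timestamp(year=start_year + n_seasons, month=1, day=1)
        weather[site_id] = _daily_series(
            rng, site_id, level, planting - pd.Timedelta(days=5), end
        )
        phases[site_id] = pw
        rows.append(
            {
                "site_id": site_id,
                "field_id": None,
                "kind": "station",
                "season": None,
                "planting_date": planting,
                "level": level,
                "is_cold": False,
            }
        )
    return Environment(sites=pd.DataFrame(rows), weather=weather, phases=phases)


def gen_multiyear_weather(
    n_points: int,
    start_year: int = 2001,
    n_years: int = 15,
    seed: int = 0,
    cold_fraction: float = 0.3,
    station_level: float = 16.0,
    warm_level: float = 16.5,
    cold_level: float = 10.5,
) -> tuple[dict[str, DailyWeather], dict[str, bool]]:
    """Historical-style daily weather for extrapolation target points.

    Each point gets one continuous series spanning ``n_years`` calendar
    years; round(cold_fraction * n_points) points are cold.  Returns
    (weather by point, is_cold flag by point).
    """
    rng = np.random.default_rng(seed)
    n_cold = int(round(cold_fraction * n_points))
    cold = set(rng.choice(n_points, size=n_cold, replace=False).tolist())
    weather: dict[str, DailyWeather] = {}
    is_cold: dict[str, bool] = {}
    start = pd.Timestamp(year=start_year, month=1, day=1)
    end = pd.Timestamp(year=start_year + n_years, month=6, day=30)
    for i in range(n_points):
        pid = f"PT{i + 1:04d}"
        level = (
            cold_level + rng.normal(0, 0.8) if i in cold else warm_level + rng.normal(0, 0.3)
        )
        weather[pid] = _daily_series(rng, pid, level, start, end)
        is_cold[pid] = i in cold
    return weather, is_cold


# ---------------------------------------------------------------------------
# True worths
# ---------------------------------------------------------------------------

def gen_true_worths(
    markers: pd.DataFrame,
    covariates: pd.DataFrame | pd.Series,
    model: TrueModel,
) -> pd.DataFrame:
    """Per-field normalized worth vectors implied by the true model.

    ``covariates`` must contain the model's switch covariate for every
    field (a DataFrame column or a Series).  The shift activates on
    *strict* exceedance of the threshold; for each field
    log-worth(i) = base(i) + shift(i) * 1[x > threshold], and worths are
    softmax-normalized to sum to one.
    """
    if isinstance(covariates, pd.Series):
        x = covariates.astype(float)
    else:
        if model.switch_covariate not in covariates.columns:
            raise KeyError(
                f"covariate {model.switch_covariate!r} missing from covariate table"
            )
        x = covariates[model.switch_covariate].astype(float)
    above = (x > model.switch_threshold).to_numpy()
    lw = model.log_worth_base[None, :] + np.outer(above, model.log_worth_shift)
    w = np.exp(lw - lw.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    return pd.DataFrame(w, index=x.index, columns=list(model.items))


# ---------------------------------------------------------------------------
# Tricot design and trial
# ---------------------------------------------------------------------------

def gen_tricot_design(
    test_items: Sequence[str],
    check: str,
    fields: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Allocate 3 test genotypes + 1 check per farm field.

    Balanced greedy allocation: each field receives the three currently
    least-used test genotypes (random tie-break), keeping the max/min
    assignment-frequency ratio small.  ``fields`` must carry field_id,
    season, site_id and planting_date columns.
    """
    test_items = [str(t) for t in test_items]
    if check in test_items:
        raise ValueError("check must not be among the test items")
    if len(test_items) < 3:
        raise ValueError("need at least 3 test items")
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(test_items))
    rows = []
    for _, f in fields.iterrows():
        order = np.lexsort((rng.random(len(test_items)), counts))
        chosen = [test_items[i] for i in order[:3]]
        counts[order[:3]] += 1
        rng.shuffle(chosen)
        rows.append(
            {
                "field_id": f["field_id"],
                "season": f["season"],
                "site_id": f["site_id"],
                "planting_date": f["planting_date"],
                "entry_1": chosen[0],
                "entry_2": chosen[1],
                "entry_3": chosen[2],
                "check": check,
            }
        )
    return pd.DataFrame(rows)


def design_entries(design: pd.DataFrame) -> list[list[str]]:
    return [
        [r["entry_1"], r["entry_2"], r["entry_3"], r["check"]]
        for _, r in design.iterrows()
    ]


def gen_tricot_trial(
    design: pd.DataFrame,
    worths: pd.DataFrame,
    model: TrueModel,
    seed: int = 0,
) -> tuple[RankingSet, pd.DataFrame]:
    """Sample farmer rankings and per-plot grain yields.

    Rankings are drawn from the sequential Luce process (winner chosen
    with probability alpha_i / sum alpha among remaining entries,
    implemented via the equivalent Gumbel-argmax construction).  Plot GY
    is ``yield_base + yield_scale * centred log-worth + N(0, noise_sd)``
    truncated at zero.
    """
    rng = np.random.default_rng(seed)
    items = list(worths.columns)
    index = {it: i for i, it in enumerate(items)}
    entries = design_entries(design)
    for row in entries:
        for it in row:
            if it not in index:
                raise ValueError(f"design entry {it!r} has no worth")
    if (worths.to_numpy() <= 0).any():
        raise ValueError("worths must be positive")

    entry_idx = np.array([[index[it] for it in row] for row in entries])
    W = worths.to_numpy(float)
    field_pos = {f: i for i, f in enumerate(worths.index)}
    rows_pos = np.array([field_pos[f] for f in design["field_id"]])
    logw = np.log(W)

    # rankings: per-field Gumbel-argmax over the field's 4 entries
    g = rng.gumbel(size=entry_idx.shape)
    scores = logw[rows_pos[:, None], entry_idx] + g
    order = np.argsort(-scores, axis=1)
    ranked_idx = np.take_along_axis(entry_idx, order, axis=1)

    records = []
    for i, (_, drow) in enumerate(design.iterrows()):
        ordering = tuple(items[j] for j in ranked_idx[i])
        records.append(
            Ranking(group=str(drow["field_id"]), ordering=ordering, season=str(drow["season"]))
        )
    rankings = RankingSet(records, items=items)

    # grain yield per plot: centred log-worths within field
    centred = logw - logw.mean(axis=1, keepdims=True)
    gy_rows = []
    noise = rng.normal(0, model.noise_sd, size=entry_idx.shape) if model.noise_sd > 0 else np.zeros(entry_idx.shape)
    for i, (_, drow) in enumerate(design.iterrows()):
        for k in range(4):
            j = entry_idx[i, k]
            gy = model.yield_base + model.yield_scale * centred[rows_pos[i], j] + noise[i, k]
            gy_rows.append(
                {
                    "field_id": drow["field_id"],
                    "season": drow["season"],
                    "item": items[j],
                    "gy": max(0.0, float(gy)),
                }
            )
    return rankings, pd.DataFrame(gy_rows)


# ---------------------------------------------------------------------------
# Station design and trial
# ---------------------------------------------------------------------------

def gen_station_design(
    genotypes: Sequence[str],
    n_reps: int = 2,
    locations: Sequence[str] = ("Geregera", "Hagreselam"),
    seasons: Sequence[str] = ("2012", "2013"),
    block_size: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated incomplete-block station layout: per location-season,
    every genotype appears once per replicate, shuffled into blocks of
    ``block_size`` plots (n_plots = n_genotypes * n_reps)."""
    rng = np.random.default_rng(seed)
    genotypes = [str(g) for g in genotypes]
    rows = []
    for loc in locations:
        for season in seasons:
            for rep in range(1, n_reps + 1):
                perm = list(rng.permutation(genotypes))
                for pos, g in enumerate(perm):
                    rows.append(
                        {
                            "location": loc,
                            "season": season,
                            "replicate": rep,
                            "block": pos // block_size + 1,
                            "genotype": g,
                        }
                    )
    df = pd.DataFrame(rows)
    df.insert(0, "plot_id", [f"P{i + 1:05d}" for i in range(len(df))])
    return df


def gen_station_trial(
    design: pd.DataFrame,
    model: TrueModel,
    seed: int = 0,
    condition_above: bool | Mapping[tuple[str, str], bool] = True,
    loc_effect_sd: float = 0.5,
    rep_sd: float = 0.2,
    block_sd: float = 0.15,
    n_raters: tuple[int, int] = (15, 15),
    oa_seasons: Sequence[str] | None = None,
    oa_slope: float = 1.2,
    oa_noise_sd: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Station plot table with GY plus an overall-appreciation table.

    GY per plot = yield_base + location-season effect + genetic value +
    replicate and block effects + noise.  OA is collected per rater
    (tagged men/women) as a discretized noisy monotone transform of the
    genetic value on the integer 1..5 scale (no half values), by default
    only in the first season, mirroring a single participatory scoring
    campaign.
    """
    rng = np.random.default_rng(seed)
    items = list(model.items)
    index = {g: i for i, g in enumerate(items)}
    unknown = set(design["genotype"]) - set(items)
    if unknown:
        raise ValueError(f"design genotypes missing from model: {sorted(unknown)}")

    def above(loc: str, season: str) -> bool:
        if isinstance(condition_above, Mapping):
            return bool(condition_above[(loc, season)])
        return bool(condition_above)

    lw_above = model.log_worths(True)
    lw_below = model.log_worths(False)
    lw_above = lw_above - lw_above.mean()
    lw_below = lw_below - lw_below.mean()

    env_keys = sorted(set(zip(design["location"], design["season"])))
    env_eff = {k: rng.normal(0, loc_effect_sd) for k in env_keys}
    rep_eff = {
        (loc, season, rep): rng.normal(0, rep_sd)
        for (loc, season) in env_keys
        for rep in sorted(set(design["replicate"]))
    }
    block_keys = sorted(
        set(zip(design["location"], design["season"], design["replicate"], design["block"]))
    )
    block_eff = {k: rng.normal(0, block_sd) for k in block_keys}

    g_idx = design["genotype"].map(index).to_numpy()
    gvals = np.empty(len(design))
    for i, (_, row) in enumerate(design.iterrows()):
        lw = lw_above if above(row["location"], row["season"]) else lw_below
        gvals[i] = model.yield_scale * lw[g_idx[i]]
    noise = rng.normal(0, model.noise_sd, size=len(design))
    gy = (
        model.yield_base
        + np.array([env_eff[(r["location"], r["season"])] for _, r in design.iterrows()])
        + gvals
        + np.array(
            [rep_eff[(r["location"], r["season"], r["replicate"])] for _, r in design.iterrows()]
        )
        + np.array(
            [
                block_eff[(r["location"], r["season"], r["replicate"], r["block"])]
                for _, r in design.iterrows()
            ]
        )
        + noise
    )
    plots = design.copy()
    plots["gy"] = np.maximum(0.0, gy)

    if oa_seasons is None:
        oa_seasons = [sorted(set(design["season"]))[0]]
    oa_rows = []
    for loc in sorted(set(design["location"])):
        for season in oa_seasons:
            sub = plots[(plots["location"] == loc) & (plots["season"] == season)]
            if sub.empty:
                continue
            lw = lw_above if above(loc, season) else lw_below
            sd = lw.std()
            z = lw / sd if sd > 0 else np.zeros_like(lw)
            raters = [(f"{loc}_M{i + 1:02d}", "man") for i in range(n_raters[0])] + [
                (f"{loc}_W{i + 1:02d}", "woman") for i in range(n_raters[1])
            ]
            zg = z[sub["genotype"].map(index).to_numpy()]
            for rater, gender in raters:
                raw = 3.0 + oa_slope * zg + (
                    rng.normal(0, oa_noise_sd, size=len(sub)) if oa_noise_sd > 0 else 0.0
                )
                scores = np.clip(np.rint(raw), 1, 5).astype(int)
                for (_, prow), sc in zip(sub.iterrows(), scores):
                    oa_rows.append(
                        {
                            "location": loc,
                            "season": season,
                            "plot_id": prow["plot_id"],
                            "genotype": prow["genotype"],
                            "rater": rater,
                            "gender": gender,
                            "oa": int(sc),
                        }
                    )
    return plots, pd.DataFrame(oa_rows)


# ---------------------------------------------------------------------------
# Whole-scenario orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Every knob of the synthetic study in one (YAML-serializable) place.

    Defaults describe the scaled-down standard scenario used throughout
    the test-suite and examples; `paper_design()` returns the full-size
    layout of the original study for count fixtures.
    """

    n_genotypes: int = 100
    n_farm_genotypes: int = 15
    n_snps: int = 300
    maf_low: float = 0.05
    maf_high: float = 0.5
    season_sizes: tuple[int, ...] = (80, 160, 120)
    n_stations: int = 2
    station_seasons: tuple[str, ...] = ("2012", "2013")
    n_reps: int = 2
    block_size: int = 20
    cold_fraction: float = 0.5
    phase_durations: tuple[int, int, int] = (60, 95, 120)
    base_sd: float = 0.75
    shift_sd: float = 2.0
    switch_covariate: str = "minNT_veg"
    switch_threshold: float = 11.5
    yield_scale: float = 0.35
    yield_base: float = 2.5
    noise_sd: float = 0.4
    n_raters: tuple[int, int] = (5, 5)
    oa_noise_sd: float = 0.7
    climate_indices: tuple[str, ...] = (
        "minNT", "maxNT", "meanNT", "meanDT", "GDD", "rain", "maxDry",
    )

    @classmethod
    def paper_design(cls) -> "ScenarioConfig":
        """Full-size layout: 400 station genotypes, 41 on farms, 1,165
        fields over seasons of 179/651/335, 2 stations x 2 seasons x 2
        replicates (800 plots per station field, 3,200 in total)."""
        return cls(
            n_genotypes=400,
            n_farm_genotypes=41,
            season_sizes=(179, 651, 335),
            n_raters=(15, 15),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("season_sizes", "station_seasons", "phase_durations", "n_raters",
                    "climate_indices"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Scenario:
    """A fully generated synthetic study, ready for analysis."""

    config: ScenarioConfig
    seed: int
    markers: pd.DataFrame
    model: TrueModel
    env: Environment
    covariates: pd.DataFrame
    design: pd.DataFrame
    true_worths: pd.DataFrame
    oa_rankings: RankingSet
    farm_plots: pd.DataFrame
    gy_rankings: RankingSet
    station_design: pd.DataFrame
    station_plots: pd.DataFrame
    station_oa: pd.DataFrame
    farm_items: tuple[str, ...]
    check: str


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in (np.random.SeedSequence(seed).generate_state(n) % (2**31))]


def generate_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Generate a complete synthetic study from one config and seed."""
    config = config or ScenarioConfig()
    s_mark, s_model, s_env, s_design, s_trial, s_stdes, s_sttr, s_pick = _child_seeds(seed, 8)

    markers = gen_markers(
        config.n_genotypes, config.n_snps, config.maf_low, config.maf_high, seed=s_mark
    )
    model = gen_true_model(
        markers,
        seed=s_model,
        base_sd=config.base_sd,
        shift_sd=config.shift_sd,
        switch_covariate=config.switch_covariate,
        switch_threshold=config.switch_threshold,
        yield_scale=config.yield_scale,
        yield_base=config.yield_base,
        noise_sd=config.noise_sd,
    )
    env = gen_environment(
        n_fields=sum(config.season_sizes),
        n_seasons=len(config.season_sizes),
        n_stations=config.n_stations,
        seed=s_env,
        cold_fraction=config.cold_fraction,
        season_sizes=config.season_sizes,
        phase_durations=config.phase_durations,
    )
    farm = env.farm_fields()
    covariates = compute_covariate_table(
        {f: env.weather[f] for f in farm["field_id"]},
        {f: env.phases[f] for f in farm["field_id"]},
        index_set=config.climate_indices,
    )

    rng_pick = np.random.default_rng(s_pick)
    all_ids = list(markers.index)
    check = all_ids[-1]
    pool = all_ids[:-1]
    farm_items = tuple(
        sorted(rng_pick.choice(pool, size=config.n_farm_genotypes, replace=False))
    )
    design = gen_tricot_design(farm_items, check, farm, seed=s_design)
    true_worths = gen_true_worths(markers, covariates, model)
    oa_rankings, farm_plots = gen_tricot_trial(design, true_worths, model, seed=s_trial)
    gy_rankings = rank_from_measures(
        farm_plots.rename(columns={"field_id": "group", "gy": "value"}),
        direction="higher_is_better",
    )

    station_design = gen_station_design(
        all_ids,
        n_reps=config.n_reps,
        seasons=config.station_seasons,
        block_size=config.block_size,
        seed=s_stdes,
    )
    station_plots, station_oa = gen_station_trial(
        station_design,
        model,
        seed=s_sttr,
        condition_above=True,  # stations sit on the warm side of the switch
        n_raters=config.n_raters,
        oa_noise_sd=config.oa_noise_sd,
    )
    return Scenario(
        config=config,
        seed=seed,
        markers=markers,
        model=model,
        env=env,
        covariates=covariates,
        design=design,
        true_worths=true_worths,
        oa_rankings=oa_rankings,
        farm_plots=farm_plots,
        gy_rankings=gy_rankings,
        station_design=station_design,
        station_plots=station_plots,
        station_oa=station_oa,
        farm_items=farm_items,
        check=check,
    )


def write_scenario(scenario: Scenario, outdir) -> list[str]:
    """Write the canonical CSVs (rankings long format, farm plots,
    station plots + OA, markers, weather, covariates) plus the scenario
    config; returns the file names written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(os.path.join(outdir, name), **kw)
        written.append(name)

    write_rankings(scenario.oa_rankings, os.path.join(outdir, "rankings_oa_long.csv"))
    written.append("rankings_oa_long.csv")
    save(scenario.farm_plots, "farm_plots.csv", index=False)
    save(scenario.station_plots, "station_plots.csv", index=False)
    save(scenario.station_oa, "station_oa.csv", index=False)
    save(scenario.markers, "markers.csv", index_label="genotype")
    save(scenario.covariates, "covariates.csv", index_label="site_id")
    save(scenario.design, "tricot_design.csv", index=False)
    wx = pd.concat(
        [w.data.assign(site_id=sid) for sid, w in scenario.env.weather.items()],
        ignore_index=True,
    )[["site_id", "date", "tmin", "tmax", "precip"]]
    save(wx, "weather.csv", index=False)
    scenario.config.to_yaml(os.path.join(outdir, "scenario_config.yaml"))
    written.append("scenario_config.yaml")
    return written
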