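import itertools
import math

import numpy as np
import pandas as pd
import pytest

from plbreed.plackett_luce import sample_orderings
from plbreed.synthetic_data import (
    ScenarioConfig,
    TrueModel,
    gen_environment,
    gen_markers,
    gen_station_design,
    gen_station_trial,
    gen_tricot_design,
    gen_tricot_trial,
    gen_true_model,
    gen_true_worths,
    generate_scenario,
)


class TestMarkers:
    def test_maf_half_columns_average_one(self):
        m = gen_markers(400, 100, 0.5, 0.5, seed=3)
        se = math.sqrt(2 * 0.5 * 0.5 / 400)
        assert np.all(np.abs(m.mean(axis=0) - 1.0) < 4 * se)

    def test_same_seed_reproduces(self):
        a = gen_markers(10, 100, 0.1, 0.5, seed=11)
        b = gen_markers(10, 100, 0.1, 0.5, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_column_frequency_within_3_se_of_drawn_maf(self):
        m = gen_markers(200, 500, 0.05, 0.5, seed=7)
        maf = m.attrs["maf"]
        freq = m.mean(axis=0).to_numpy() / 2
        se = np.sqrt(maf * (1 - maf) / (2 * 200))
        assert (np.abs(freq - maf) <= 3 * se).mean() > 0.98

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            gen_markers(10, 10, 0.6, 0.7, seed=0)
        with pytest.raises(ValueError):
            gen_markers(10, 10, 0.3, 0.1, seed=0)

    def test_dosages_in_0_1_2(self):
        m = gen_markers(30, 50, 0.05, 0.5, seed=5)
        assert set(np.unique(m.to_numpy())) <= {0, 1, 2}


class TestEnvironment:
    def test_cold_fraction_site_count(self):
        env = gen_environment(100, 3, 2, seed=4, cold_fraction=0.3)
        farm = env.farm_fields()
        station_means = [
            env.weather[s].data["tmin"].mean() for s in env.stations()["site_id"]
        ]
        coldest_station = min(station_means)
        n_below = sum(
            env.weather[f].data["tmin"].mean() < coldest_station
            for f in farm["field_id"]
        )
        assert 25 <= n_below <= 35

    def test_every_day_tmin_below_tmax(self):
        env = gen_environment(20, 2, 1, seed=9)
        for w in env.weather.values():
            assert (w.data["tmin"] <= w.data["tmax"]).all()

    def test_fixed_seed_reproduces_series(self):
        a = gen_environment(10, 2, 1, seed=42)
        b = gen_environment(10, 2, 1, seed=42)
        for site in a.weather:
            pd.testing.assert_frame_equal(a.weather[site].data, b.weather[site].data)

    def test_weather_covers_phase_windows(self):
        env = gen_environment(10, 2, 1, seed=2)
        for f in env.farm_fields()["field_id"]:
            pw = env.phases[f]
            env.weather[f].window(pw.planting_date, pw.harvest_date)  # no CoverageError


class TestTrueWorths:
    def _model(self, n=6, shift=None):
        base = np.linspace(-1, 1, n)
        shift_arr = np.zeros(n) if shift is None else np.asarray(shift, float)
        return TrueModel(
            items=tuple(f"G{i}" for i in range(n)),
            log_worth_base=base - base.mean(),
            switch_covariate="x",
            switch_threshold=11.5,
            log_worth_shift=shift_arr,
            yield_scale=0.3,
            noise_sd=0.0,
        )

    def test_zero_shift_gives_identical_worths_everywhere(self):
        model = self._model()
        cov = pd.Series([5.0, 11.5, 20.0], index=["f1", "f2", "f3"], name="x")
        w = gen_true_worths(None, cov, model)
        assert np.allclose(w.loc["f1"], w.loc["f3"])
        assert np.allclose(w.sum(axis=1), 1.0)

    def test_field_exactly_at_threshold_takes_base_worths(self):
        shift = np.zeros(6)
        shift[0] = 5.0
        model = self._model(shift=shift)
        cov = pd.Series([11.5, 11.5001], index=["at", "above"], name="x")
        w = gen_true_worths(None, cov, model)
        base_only = gen_true_worths(None, pd.Series([0.0], index=["at"], name="x"),
                                    self._model())
        assert np.allclose(w.loc["at"], base_only.loc["at"])
        assert w.loc["above", "G0"] > w.loc["at", "G0"]

    def test_positive_shift_strictly_improves_rank_above_threshold(self):
        shift = np.zeros(6)
        shift[2] = 4.0
        model = self._model(shift=shift)
        cov = pd.Series([10.0, 13.0], index=["below", "above"], name="x")
        w = gen_true_worths(None, cov, model)
        rank_below = (w.loc["below"] > w.loc["below", "G2"]).sum()
        rank_above = (w.loc["above"] > w.loc["above", "G2"]).sum()
        assert rank_above < rank_below

    def test_missing_covariate_rejected(self):
        model = self._model()
        cov = pd.DataFrame({"y": [1.0]}, index=["f1"])
        with pytest.raises(KeyError):
            gen_true_worths(None, cov, model)


def _fields_frame(n, season="S1"):
    return pd.DataFrame(
        {
            "field_id": [f"F{i:04d}" for i in range(n)],
            "season": season,
            "site_id": [f"F{i:04d}" for i in range(n)],
            "planting_date": pd.Timestamp("2013-07-01"),
        }
    )


class TestTricot:
    def test_design_balance_ratio(self):
        items = [f"G{i:02d}" for i in range(20)]
        for seed in (0, 1):
            d = gen_tricot_design(items, "CHK", _fields_frame(300), seed=seed)
            counts = (
                d[["entry_1", "entry_2", "entry_3"]].stack().value_counts()
            )
            assert counts.max() / counts.min() <= 1.5

    def test_each_field_has_four_distinct_entries(self):
        d = gen_tricot_design([f"G{i}" for i in range(10)], "CHK", _fields_frame(50), seed=3)
        for _, row in d.iterrows():
            entries = {row["entry_1"], row["entry_2"], row["entry_3"], row["check"]}
            assert len(entries) == 4

    def test_dominant_worth_ranks_first_almost_surely(self):
        items = ["A", "B", "C", "CHK"]
        model = TrueModel(
            items=tuple(items),
            log_worth_base=np.zeros(4),
            switch_covariate="x",
            switch_threshold=0.0,
            log_worth_shift=np.zeros(4),
            yield_scale=0.3,
            noise_sd=0.1,
        )
        n = 1000
        fields = _fields_frame(n)
        design = gen_tricot_design(["A", "B", "C"], "CHK", fields, seed=1)
        w = pd.DataFrame(
            np.tile([1e6, 1.0, 1.0, 1.0], (n, 1)), index=fields["field_id"],
            columns=items,
        )
        w = w.div(w.sum(axis=1), axis=0)
        rankings, _ = gen_tricot_trial(design, w, model, seed=5)
        firsts = sum(rec.ordering[0] == "A" for rec in rankings.records)
        assert firsts >= 999

    def test_zero_noise_gy_order_equals_worth_order(self):
        items = ["A", "B", "C", "CHK"]
        model = TrueModel(
            items=tuple(items),
            log_worth_base=np.array([1.0, 0.5, -0.5, 0.0]),
            switch_covariate="x",
            switch_threshold=0.0,
            log_worth_shift=np.zeros(4),
            yield_scale=0.3,
            noise_sd=0.0,
        )
        fields = _fields_frame(20)
        design = gen_tricot_design(["A", "B", "C"], "CHK", fields, seed=2)
        lw = model.log_worth_base
        w = pd.DataFrame(
            np.tile(np.exp(lw) / np.exp(lw).sum(), (20, 1)),
            index=fields["field_id"], columns=items,
        )
        _, plots = gen_tricot_trial(design, w, model, seed=3)
        for _, sub in plots.groupby("field_id"):
            vals = sub.set_index("item")["gy"]
            order = list(vals.sort_values(ascending=False).index)
            truth = sorted(vals.index, key=lambda it: -lw[items.index(it)])
            assert order == truth

    def test_luce_sampler_matches_product_form_probabilities(self):
        """Gumbel-argmax sampling reproduces the product-form ordering
        probabilities for worths (0.5, 0.3, 0.2) within 3 MC errors."""
        worths = np.array([0.5, 0.3, 0.2])
        rng = np.random.default_rng(99)
        n = 50_000
        entries = np.tile(np.arange(3), (n, 1))
        draws = sample_orderings(np.log(worths), entries, rng)
        seen = {}
        for perm in map(tuple, draws):
            seen[perm] = seen.get(perm, 0) + 1
        for perm in itertools.permutations(range(3)):
            p = 1.0
            rem = list(perm)
            while len(rem) > 1:
                p *= worths[rem[0]] / worths[rem].sum()
                rem = rem[1:]
            obs = seen.get(perm, 0) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) <= 3 * se


class TestStation:
    def test_plot_counts_match_design_arithmetic(self):
        design = gen_station_design(
            [f"G{i}" for i in range(100)], n_reps=2,
            locations=("L1", "L2"), seasons=("2012", "2013"), seed=1,
        )
        assert len(design) == 100 * 2 * 2 * 2
        per_field = design.groupby(["location", "season"]).size()
        assert (per_field == 200).all()

    def test_zero_variance_components_give_constant_oa_per_genotype(self):
        mk = gen_markers(20, 50, seed=1)
        model = gen_true_model(mk, seed=2, base_sd=0.5, shift_sd=0.0, noise_sd=0.0)
        design = gen_station_design(mk.index, n_reps=2, seasons=("2012",), seed=3)
        plots, oa = gen_station_trial(
            design, model, seed=4,
            loc_effect_sd=0.0, rep_sd=0.0, block_sd=0.0,
            n_raters=(2, 2), oa_noise_sd=0.0,
        )
        spread = oa.groupby("genotype")["oa"].nunique()
        assert (spread == 1).all()

    def test_oa_scores_are_integers_one_to_five(self):
        mk = gen_markers(15, 40, seed=5)
        model = gen_true_model(mk, seed=6)
        design = gen_station_design(mk.index, n_reps=2, seasons=("2012",), seed=7)
        _, oa = gen_station_trial(design, model, seed=8, n_raters=(3, 3))
        assert oa["oa"].between(1, 5).all()
        assert oa["oa"].dtype.kind == "i"
        assert set(oa["gender"]) == {"man", "woman"}


def test_generate_scenario_is_deterministic_and_coherent():
    cfg = ScenarioConfig(
        n_genotypes=25, n_farm_genotypes=8, n_snps=60,
        season_sizes=(12, 16, 12), n_raters=(2, 2),
    )
    a = generate_scenario(cfg, seed=5)
    b = generate_scenario(cfg, seed=5)
    pd.testing.assert_frame_equal(a.markers, b.markers)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    assert a.oa_rankings == b.oa_rankings
    assert len(a.farm_plots) == 4 * sum(cfg.season_sizes)
    assert set(a.design["check"]) == {a.check}
    # every ranked item is a farm item or the check
    ranked = set(a.oa_rankings.ranked_items())
    assert ranked <= set(a.farm_items) | {a.check}
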