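import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from plbreed.plackett_luce import (
    IdentifiabilityError,
    WorthVector,
    fit_pl,
    fit_pl_genomic,
    log_likelihood,
)
from plbreed.rankings import Ranking, RankingSet

from conftest import simulate_rankings


def brute_force_loglik(orderings, worths):
    """Independent product-form likelihood: explicit stagewise evaluation."""
    total = 0.0
    for ordering in orderings:
        remaining = list(ordering)
        while len(remaining) > 1:
            total += math.log(worths[remaining[0]] / sum(worths[i] for i in remaining))
            remaining.pop(0)
    return total


class TestLogLikelihood:
    def test_two_equal_items_give_log_half(self):
        rs = RankingSet([Ranking("f1", ("A", "B"))])
        w = WorthVector(("A", "B"), np.array([0.5, 0.5]))
        assert log_likelihood(rs, w) == pytest.approx(math.log(0.5))

    def test_three_item_hand_evaluation(self):
        # P(A>B>C) = 0.5 * (0.3 / 0.5) = 0.3
        rs = RankingSet([Ranking("f1", ("A", "B", "C"))])
        w = WorthVector(("A", "B", "C"), np.array([0.5, 0.3, 0.2]))
        assert log_likelihood(rs, w) == pytest.approx(math.log(0.3))

    def test_single_item_ranking_contributes_zero(self):
        rs = RankingSet([Ranking("f1", ("A",))], items=("A", "B"))
        w = WorthVector(("A", "B"), np.array([0.9, 0.1]))
        assert log_likelihood(rs, w) == 0.0

    def test_matches_independent_product_form(self, rng):
        items = ["A", "B", "C", "D"]
        rs = simulate_rankings(rng.normal(size=4), items, 30, 3, rng)
        w = WorthVector.from_unnormalized(items, rng.uniform(0.2, 2.0, 4))
        expected = brute_force_loglik(
            [r.ordering for r in rs.records], dict(zip(items, w.worths))
        )
        assert log_likelihood(rs, w) == pytest.approx(expected)

    def test_weighted_records_scale_contributions(self):
        r1 = RankingSet([Ranking("f1", ("A", "B"), weight=3.0)])
        r2 = RankingSet([Ranking("f1", ("A", "B"))])
        w = WorthVector(("A", "B"), np.array([0.7, 0.3]))
        assert log_likelihood(r1, w) == pytest.approx(3 * log_likelihood(r2, w))


def test_gauge_invariance_of_log_worths():
    """Adding a constant to all log-worths leaves the model unchanged."""
    items = ("A", "B", "C")
    lw = np.array([0.3, -0.2, 1.1])
    assert np.allclose(
        WorthVector.from_log(items, lw).worths,
        WorthVector.from_log(items, lw + 5.0).worths,
    )


class TestFitPL:
    def test_two_item_closed_form(self):
        rs = RankingSet(
            [Ranking(f"f{i}", ("A", "B")) for i in range(3)] + [Ranking("f3", ("B", "A"))]
        )
        fit = fit_pl(rs)
        assert fit.worths["A"] == pytest.approx(0.75, abs=1e-6)
        assert fit.worths["B"] == pytest.approx(0.25, abs=1e-6)

    def test_symmetric_data_gives_uniform_worths(self):
        records = [
            Ranking(f"f{i}", perm)
            for i, perm in enumerate(itertools.permutations(("A", "B", "C")))
        ]
        fit = fit_pl(RankingSet(records))
        assert np.allclose(fit.worths.worths, 1 / 3, atol=1e-8)

    def test_matches_brute_force_grid_on_three_items(self, rng):
        items = ["A", "B", "C"]
        rs = simulate_rankings(np.array([0.8, 0.0, -0.5]), items, 20, 3, rng)
        orderings = [r.ordering for r in rs.records]
        # independent oracle: refined grid search on the 2-simplex
        best, arg = -np.inf, None
        grid = np.linspace(0.01, 0.98, 98)
        for a in grid:
            for b in grid:
                c = 1.0 - a - b
                if c <= 0.005:
                    continue
                ll = brute_force_loglik(orderings, {"A": a, "B": b, "C": c})
                if ll > best:
                    best, arg = ll, (a, b, c)
        a0, b0, _ = arg
        fine = np.arange(-0.01, 0.0101, 0.0005)
        for da in fine:
            for db in fine:
                a, b = a0 + da, b0 + db
                c = 1.0 - a - b
                if min(a, b, c) <= 0:
                    continue
                ll = brute_force_loglik(orderings, {"A": a, "B": b, "C": c})
                if ll > best:
                    best, arg = ll, (a, b, c)
        fit = fit_pl(rs)
        assert fit.worths.worths == pytest.approx(np.array(arg), abs=1e-3)
        assert fit.log_likelihood == pytest.approx(best, abs=1e-3)

    def test_deviance_is_minus_twice_loglik(self, abc_rankings):
        fit = fit_pl(abc_rankings)
        assert fit.deviance == pytest.approx(-2 * fit.log_likelihood)

    def test_disconnected_graph_raises_naming_components(self):
        rs = RankingSet([Ranking("f1", ("A", "B")), Ranking("f2", ("A", "B"))])
        with pytest.raises(IdentifiabilityError, match="A") as exc:
            fit_pl(rs)
        assert len(exc.value.components) == 2

    def test_optimum_beats_uniform(self, rng):
        items = [f"I{i}" for i in range(6)]
        rs = simulate_rankings(rng.normal(size=6), items, 60, 4, rng)
        fit = fit_pl(rs)
        uniform = WorthVector(tuple(items), np.full(6, 1 / 6))
        assert fit.log_likelihood >= log_likelihood(rs, uniform) - 1e-9


@given(st.integers(min_value=0, max_value=10_000))
def test_fitted_worths_form_probability_vector(seed):
    rng = np.random.default_rng(seed)
    items = ["A", "B", "C", "D"]
    rs = simulate_rankings(rng.normal(size=4), items, 25, 4, rng)
    fit = fit_pl(rs)
    assert np.all(fit.worths.worths > 0)
    assert fit.worths.worths.sum() == pytest.approx(1.0, abs=1e-10)


class TestGenomicMAP:
    def _kinship(self, items, rng=None, identity=True):
        n = len(items)
        if identity:
            K = np.eye(n)
        else:
            A = rng.normal(size=(n, n + 4))
            K = A @ A.T / (n + 4)
        return pd.DataFrame(K, index=items, columns=items)

    def test_weak_prior_approaches_mle(self, abc_rankings):
        K = self._kinship(list(abc_rankings.items))
        mle = fit_pl(abc_rankings)
        mapfit = fit_pl_genomic(abc_rankings, K, prior_scale=1e6)
        assert mapfit.worths.worths == pytest.approx(mle.worths.worths, abs=2e-3)

    def test_dominating_prior_gives_uniform(self, abc_rankings):
        K = self._kinship(list(abc_rankings.items))
        mapfit = fit_pl_genomic(abc_rankings, K, prior_scale=1e-8)
        assert np.allclose(mapfit.worths.worths, 1 / 3, atol=1e-3)

    def test_exchangeable_genotypes_get_equal_worths(self):
        # C and D have identical kinship rows and symmetric data
        items = ("A", "C", "D")
        K = pd.DataFrame(
            [[1.0, 0.2, 0.2], [0.2, 1.0, 1.0], [0.2, 1.0, 1.0]],
            index=items, columns=items,
        )
        rs = RankingSet(
            [
                Ranking("f1", ("A", "C")),
                Ranking("f2", ("A", "D")),
                Ranking("f3", ("C", "A")),
                Ranking("f4", ("D", "A")),
            ]
        )
        fit = fit_pl_genomic(rs, K, prior_scale=1.0)
        assert fit.worths["C"] == pytest.approx(fit.worths["D"], abs=1e-6)

    def test_identifiable_on_disconnected_graph(self):
        items = ("A", "B")
        rs = RankingSet([Ranking("f1", ("A", "B"))])
        K = self._kinship(items)
        fit = fit_pl_genomic(rs, K, prior_scale=1.0)
        assert fit.worths["A"] > fit.worths["B"]

    def test_unranked_item_shrinks_to_relatives(self):
        # E never ranked but nearly identical to the strong item A
        items = ("A", "B", "E")
        K = pd.DataFrame(
            [[1.0, 0.0, 0.95], [0.0, 1.0, 0.0], [0.95, 0.0, 1.0]],
            index=items, columns=items,
        )
        rs = RankingSet(
            [Ranking(f"f{i}", ("A", "B")) for i in range(8)]
            + [Ranking("f9", ("B", "A"))]
        )
        fit = fit_pl_genomic(rs, K, prior_scale=1.0)
        assert fit.worths["E"] > fit.worths["B"]

    def test_non_psd_kinship_rejected(self, abc_rankings):
        items = list(abc_rankings.items)
        K = pd.DataFrame(
            np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]]),
            index=items, columns=items,
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_pl_genomic(abc_rankings, K)
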