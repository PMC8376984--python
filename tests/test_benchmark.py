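import numpy as np
import pandas as pd
import pytest

from plbreed.benchmark import (
    clean_markers,
    fit_gblup,
    heritability,
    kinship_vanraden,
    predict_gblup,
    reml_fit,
    station_blup,
)
from plbreed.synthetic_data import (
    gen_markers,
    gen_station_design,
    gen_station_trial,
    gen_true_model,
)


class TestCleanMarkers:
    def test_complete_data_below_thresholds_passes_through(self):
        # moderate MAF keeps heterozygosity safely under the 50% cap
        m = gen_markers(200, 100, 0.05, 0.25, seed=1)
        out = clean_markers(m)
        assert out.shape == m.shape
        assert np.allclose(out.to_numpy(), m.to_numpy())

    def test_high_missing_snp_dropped(self):
        m = gen_markers(10, 5, seed=2).astype(float)
        m.iloc[:9, 0] = np.nan  # 90% missing
        out = clean_markers(m, max_missing=0.8)
        assert m.columns[0] not in out.columns
        assert out.shape[1] == 4

    def test_imputation_uses_observed_column_mean(self):
        m = gen_markers(200, 100, 0.05, 0.25, seed=3).astype(float)
        m.iloc[0, 1] = np.nan
        out = clean_markers(m)
        observed_mean = m.iloc[1:, 1].mean()
        assert out.iloc[0, 1] == pytest.approx(observed_mean)

    def test_high_heterozygosity_snp_dropped(self):
        m = gen_markers(10, 5, seed=4).astype(float)
        m.iloc[:, 2] = 1.0  # fully heterozygous
        out = clean_markers(m, max_het=0.5)
        assert m.columns[2] not in out.columns

    def test_all_dropped_is_error(self):
        m = pd.DataFrame(np.ones((4, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="removed all"):
            clean_markers(m, max_het=0.1)


class TestKinship:
    def test_hand_example_two_genotypes_two_snps(self):
        m = pd.DataFrame([[0, 2], [2, 0]], index=["g1", "g2"], columns=["s1", "s2"])
        K = kinship_vanraden(m)
        # p = (0.5, 0.5), Z = ((-1,1),(1,-1)), denominator 1
        assert np.allclose(K.to_numpy(), [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicated_genotype_rows(self):
        m = gen_markers(6, 80, seed=5)
        m.iloc[1] = m.iloc[0]
        K = kinship_vanraden(m)
        assert K.iloc[0, 1] == pytest.approx(K.iloc[0, 0])
        assert K.iloc[0, 1] == pytest.approx(K.iloc[1, 1])

    def test_mean_diagonal_near_one_under_hardy_weinberg(self):
        K = kinship_vanraden(gen_markers(300, 2000, 0.1, 0.5, seed=6))
        assert np.mean(np.diag(K.to_numpy())) == pytest.approx(1.0, abs=0.05)

    def test_symmetric_psd_for_generated_markers(self):
        for seed in (0, 1, 2):
            K = kinship_vanraden(gen_markers(30, 100, seed=seed)).to_numpy()
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_monomorphic_snps_dropped_with_warning(self):
        m = gen_markers(10, 20, seed=7)
        m.iloc[:, 0] = 2
        with pytest.warns(UserWarning, match="monomorphic"):
            kinship_vanraden(m)


def mme_solve(y, K, var_u, var_e):
    """Independent oracle: direct solve of Henderson's mixed-model
    equations for y = mu + u + e, u ~ N(0, var_u K)."""
    n = len(y)
    X = np.ones((n, 1))
    lam = var_e / var_u
    Kinv = np.linalg.inv(K + 1e-10 * np.eye(n))
    C = np.block([[X.T @ X, X.T], [X, np.eye(n) + lam * Kinv]])
    rhs = np.concatenate([X.T @ y, y])
    sol = np.linalg.solve(C, rhs)
    return sol[0], sol[1:]


class TestGBLUP:
    def test_constant_phenotype_gives_zero_genetic_variance(self):
        K = kinship_vanraden(gen_markers(10, 60, seed=1))
        y = pd.Series(3.0, index=K.index)
        m = fit_gblup(y, K)
        assert m.var_u == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(m.blups.to_numpy(), 0.0, atol=1e-6)

    def test_blups_match_direct_mme_solve(self, rng):
        K = kinship_vanraden(gen_markers(10, 200, seed=2))
        Kv = K.to_numpy()
        L = np.linalg.cholesky(Kv + 1e-8 * np.eye(10))
        y = pd.Series(2.0 + L @ rng.normal(size=10) + 0.3 * rng.normal(size=10),
                      index=K.index)
        m = fit_gblup(y, K)
        mu, u = mme_solve(y.to_numpy(), Kv, m.var_u, m.var_e)
        assert m.mu == pytest.approx(mu, abs=1e-4)
        assert m.blups.to_numpy() == pytest.approx(u, abs=1e-3)

    def test_variance_ratio_recovery(self):
        K = kinship_vanraden(gen_markers(200, 400, seed=3))
        L = np.linalg.cholesky(K.to_numpy() + 1e-8 * np.eye(200))
        errs = []
        for s in range(20):
            r = np.random.default_rng(500 + s)
            y = pd.Series(1.0 + L @ r.normal(size=200) + r.normal(0, 1, 200),
                          index=K.index)
            m = fit_gblup(y, K)
            errs.append(abs(m.var_u / m.var_e - 1.0))
        assert np.median(errs) <= 0.5

    def test_prediction_invariant_to_phenotype_shift(self, rng):
        K = kinship_vanraden(gen_markers(20, 100, seed=4))
        train = list(K.index[:15])
        targets = list(K.index[15:])
        y = pd.Series(rng.normal(size=15), index=train)
        p0 = predict_gblup(fit_gblup(y, K), targets, K)
        p1 = predict_gblup(fit_gblup(y + 7.0, K), targets, K)
        assert np.allclose(p1.to_numpy(), p0.to_numpy() + 7.0, atol=1e-4)

    def test_identity_kinship_predicts_mean_out_of_sample(self, rng):
        ids = [f"g{i}" for i in range(12)]
        K = pd.DataFrame(np.eye(12), index=ids, columns=ids)
        y = pd.Series(rng.normal(size=8), index=ids[:8])
        model = fit_gblup(y, K)
        with pytest.warns(UserWarning, match="unrelated"):
            preds = predict_gblup(model, ids[8:], K)
        assert np.allclose(preds.to_numpy(), model.mu)

    def test_training_genotype_prediction_approaches_blup_for_small_ratio(self):
        K = kinship_vanraden(gen_markers(10, 200, seed=5))
        r = np.random.default_rng(6)
        L = np.linalg.cholesky(K.to_numpy() + 1e-8 * np.eye(10))
        # nearly noise-free phenotype -> lambda -> 0
        y = pd.Series(L @ r.normal(size=10) + 1e-4 * r.normal(size=10), index=K.index)
        m = fit_gblup(y, K)
        preds = predict_gblup(m, list(K.index), K)
        assert preds.to_numpy() == pytest.approx(
            (m.mu + m.blups).to_numpy(), abs=5e-3
        )

    def test_rank_transform_preserves_order(self, rng):
        K = kinship_vanraden(gen_markers(30, 100, seed=8))
        y = pd.Series(rng.normal(size=30), index=K.index)
        m = fit_gblup(y, K, rank_transform=True)
        assert m.y_train.min() == 1.0 and m.y_train.max() == 30.0


class TestREML:
    def test_matches_statsmodels_mixedlm_variance_components(self, rng):
        """Independent oracle: statsmodels MixedLM on a one-factor design."""
        import statsmodels.api as sm

        n_g, n_rep = 30, 4
        g = np.repeat(np.arange(n_g), n_rep)
        u = rng.normal(0, 1.0, n_g)
        y = 5.0 + u[g] + rng.normal(0, 0.7, n_g * n_rep)
        df = pd.DataFrame({"y": y, "g": g.astype(str), "one": 1})
        ml = sm.MixedLM.from_formula(
            "y ~ 1", groups="one", vc_formula={"g": "0 + C(g)"}, data=df
        ).fit(reml=True)
        Z = np.zeros((len(y), n_g))
        Z[np.arange(len(y)), g] = 1.0
        res = reml_fit(y, np.ones((len(y), 1)), {"g": Z})
        assert res.var_components["g"] == pytest.approx(float(ml.vcomp[0]), rel=0.02)
        assert res.var_e == pytest.approx(float(ml.scale), rel=0.02)

    def test_profile_reml_equals_direct_restricted_likelihood(self, rng):
        """Internal identity: the Henderson-MME profile equals the direct
        (H-matrix) restricted likelihood on a small problem."""
        n, q = 25, 6
        Z = rng.normal(size=(n, q)) * 0.0
        g = rng.integers(0, q, n)
        Z[np.arange(n), g] = 1.0
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + Z @ rng.normal(0, 1.2, q) + rng.normal(0, 0.8, n)
        res = reml_fit(y, X, {"g": Z})
        gamma = res.var_components["g"] / res.var_e
        H = np.eye(n) + gamma * Z @ Z.T
        Hi = np.linalg.inv(H)
        XtHiX = X.T @ Hi @ X
        P = Hi - Hi @ X @ np.linalg.inv(XtHiX) @ X.T @ Hi
        quad = float(y @ P @ y)
        var_e = quad / (n - X.shape[1])
        assert res.var_e == pytest.approx(var_e, rel=1e-4)


class TestStationBLUP:
    def _simulate(self, seed, n_geno=60, var_g=0.04, **trial_kw):
        mk = gen_markers(n_geno, 80, seed=seed)
        model = gen_true_model(
            mk, seed=seed + 1, base_sd=np.sqrt(var_g) / 0.35, shift_sd=0.0, noise_sd=0.4
        )
        design = gen_station_design(mk.index, n_reps=2, seasons=("2012",), seed=seed + 2)
        plots, _ = gen_station_trial(design, model, seed=seed + 3, n_raters=(1, 1),
                                     **trial_kw)
        return model, plots

    def test_balanced_blup_order_equals_genotype_mean_order(self):
        # block effects off: genotype means then differ only by genotype +
        # balanced env/rep contributions, so shrinkage preserves the order
        model, plots = self._simulate(seed=10, block_sd=0.0)
        blups, _ = station_blup(plots, "gy")
        means = plots.groupby("genotype")["gy"].mean()
        b = blups.loc[means.index]
        assert (
            b.rank().astype(int).to_list() == means.rank().astype(int).to_list()
        )

    def test_shrinkage_keeps_blups_inside_fixed_effect_range(self):
        _, plots = self._simulate(seed=20)
        blups, _ = station_blup(plots, "gy")
        centered = plots.groupby("genotype")["gy"].mean()
        centered = centered - centered.mean()
        ratio = blups.loc[centered.index].to_numpy() / centered.to_numpy()
        assert np.nanmax(np.abs(blups.to_numpy())) <= np.max(np.abs(centered.to_numpy())) + 1e-9

    def test_genetic_variance_recovery_median_within_50pct(self):
        errs = []
        for s in range(20):
            mk = gen_markers(200, 60, seed=900 + s)
            model = gen_true_model(mk, seed=901 + s, base_sd=0.7, shift_sd=0.0,
                                   noise_sd=0.4)
            true_vg = np.var(model.yield_scale * model.log_worth_base)
            design = gen_station_design(mk.index, n_reps=2, seasons=("2012",),
                                        seed=902 + s)
            plots, _ = gen_station_trial(design, model, seed=903 + s, n_raters=(1, 1))
            _, vc = station_blup(plots, "gy")
            errs.append(abs(vc["var_g"] - true_vg) / true_vg)
        assert np.median(errs) <= 0.5

    def test_single_rep_data_rejected(self):
        plots = pd.DataFrame(
            {
                "location": ["L1", "L1"],
                "genotype": ["g1", "g2"],
                "replicate": [1, 1],
                "gy": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="replicates"):
            station_blup(plots, "gy")


class TestHeritability:
    def test_zero_genetic_variance_gives_zero(self):
        est = heritability({"var_g": 0.0, "var_e": 1.0}, n_reps=2)
        assert est.H2 == 0.0

    def test_formula_evaluation_single_location_two_reps(self):
        est = heritability({"var_g": 1.0, "var_e": 1.0}, n_reps=2, n_locs=1)
        assert est.H2 == pytest.approx(2 / 3)

    def test_monotone_nondecreasing_in_replicates(self):
        h = [
            heritability({"var_g": 1.0, "var_e": 2.0}, n_reps=r).H2
            for r in (1, 2, 4, 8)
        ]
        assert all(a <= b for a, b in zip(h, h[1:]))

    def test_multi_location_uses_gxl_term(self):
        est = heritability(
            {"var_g": 1.0, "var_gl": 1.0, "var_e": 2.0}, n_reps=2, n_locs=2
        )
        assert est.H2 == pytest.approx(1.0 / (1.0 + 0.5 + 0.5))

    def test_narrow_sense_uses_genomic_variance(self):
        est = heritability(
            {"var_g": 1.0, "var_e": 1.0}, n_reps=2, n_locs=1, genomic_var=0.5
        )
        assert est.h2 == pytest.approx(0.5 / (0.5 + 0.5))
        assert est.h2 <= est.H2

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability({"var_g": 0.0, "var_e": 0.0}, n_reps=2)
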