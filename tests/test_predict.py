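"""Noise calibration, training plans, the four prediction models, accuracy."""

import numpy as np
import pandas as pd
import pytest

from adaptscape import gxe, predict
from adaptscape.pipeline import fixture_generator


def _simple_met(n_geno=40, n_trial=12, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, 2, n_geno)
    e = rng.normal(0, 3, n_trial)
    Y = 10 + g[:, None] + e[None, :] + rng.normal(0, 1, (n_geno, n_trial))
    ets = np.tile(["ET1", "ET2", "ET3", "ET4"], n_trial // 4)
    trials = pd.DataFrame({"trial": [f"t{j}" for j in range(n_trial)],
                           "et": ets})
    return gxe.METDataset(values=Y, trials=trials)


class TestAddNoise:
    def test_h2_one_leaves_phenotypes_unchanged(self):
        met = _simple_met()
        nm = predict.add_noise(met, 1.0, seed=1)
        assert np.array_equal(nm.noisy.values, met.values)

    def test_h2_half_sets_error_variance_to_genotypic(self):
        met = _simple_met()
        nm = predict.add_noise(met, 0.5, seed=2)
        assert np.allclose(nm.error_variances, met.values.var(axis=0, ddof=1))

    def test_realized_heritability_calibrated(self):
        met = _simple_met(n_geno=199)
        ratios = []
        for s in range(30):
            nm = predict.add_noise(met, 0.5, seed=100 + s)
            ratios.append((met.values.var(0, ddof=1)
                           / nm.noisy.values.var(0, ddof=1)).mean())
        assert abs(np.mean(ratios) - 0.5) < 0.03

    def test_ranking_of_trial_means_preserved_in_expectation(self):
        from scipy import stats

        met = _simple_met(n_geno=199, n_trial=24)
        rs = []
        for s in range(20):
            nm = predict.add_noise(met, 0.5, seed=s)
            rs.append(stats.spearmanr(met.values.mean(1),
                                      nm.noisy.values.mean(1)).statistic)
        assert np.mean(rs) > 0.95

    def test_zero_variance_trial_fails(self):
        met = _simple_met()
        met.values[:, 3] = 7.0
        with pytest.raises(ValueError, match="zero genotypic variance"):
            predict.add_noise(met, 0.5, seed=0)


class TestTrainingPlan:
    def test_stratification_exact(self):
        met = _simple_met(n_trial=24)
        plan = predict.make_training_plan(met.trials, n_splits=10, per_et=3,
                                          seed=5)
        ets = met.trials["et"].to_numpy()
        for split in plan.splits:
            assert split["train"].size == 12
            assert split["valid"].size == 12
            labels, counts = np.unique(ets[split["train"]], return_counts=True)
            assert np.all(counts == 3)
            assert np.intersect1d(split["train"], split["valid"]).size == 0

    def test_124_trials_give_108_validation(self):
        ets = np.repeat(["ET1", "ET2", "ET3", "ET4"], 31)
        trials = pd.DataFrame({"trial": [f"t{j}" for j in range(124)],
                               "et": ets})
        plan = predict.make_training_plan(trials, n_splits=20, per_et=4, seed=1)
        assert all(s["valid"].size == 108 for s in plan.splits)

    def test_small_et_deterministic_membership(self):
        ets = ["ET1"] * 6 + ["ET2"] * 2
        trials = pd.DataFrame({"trial": [f"t{j}" for j in range(8)], "et": ets})
        plan = predict.make_training_plan(trials, n_splits=5, per_et=2, seed=3)
        for split in plan.splits:
            assert {6, 7} <= set(split["train"])  # both ET2 trials always in

    def test_too_small_et_fails(self):
        trials = pd.DataFrame({"trial": ["a", "b"], "et": ["ET1", "ET2"]})
        with pytest.raises(ValueError, match="only"):
            predict.make_training_plan(trials, n_splits=2, per_et=2, seed=0)


class TestETmean:
    def test_predictions_constant_within_et(self, e2e):
        meta = e2e["meta"]
        noisy = predict.add_noise(e2e["met"], 0.5, seed=11)
        plan = predict.make_training_plan(meta, n_splits=1, per_et=2, seed=12)
        tr, va = plan.splits[0]["train"], plan.splits[0]["valid"]
        train = gxe.METDataset(values=noisy.noisy.values[:, tr],
                               trials=meta.iloc[tr].reset_index(drop=True),
                               noise_free=False)
        va_et = meta["et"].to_numpy()[va]
        fit = predict.fit_etmean(train, e2e["kinship"], va, va_et)
        for et in np.unique(va_et):
            cols = np.flatnonzero(va_et == et)
            for c in cols[1:]:
                assert np.allclose(fit.predictions[:, c],
                                   fit.predictions[:, cols[0]])

    def test_recovers_cross_et_genetic_correlation(self):
        """Known 4x4 genetic covariance is recovered within tolerance."""
        rng = np.random.default_rng(21)
        n_geno, n_per_et = 199, 8
        A = np.eye(n_geno)
        C = np.array([[1.0, 0.8, 0.3, 0.1],
                      [0.8, 1.0, 0.5, 0.2],
                      [0.3, 0.5, 1.0, 0.7],
                      [0.1, 0.2, 0.7, 1.0]])
        errs = []
        for rep in range(5):
            G = rng.multivariate_normal(np.zeros(4), C, size=n_geno)
            cols, ets = [], []
            for t in range(4):
                for j in range(n_per_et):
                    cols.append(G[:, t] + rng.normal(0, 0.3, n_geno))
                    ets.append(f"ET{t + 1}")
            Y = np.column_stack(cols)
            trials = pd.DataFrame({"trial": [f"t{j}" for j in range(32)],
                                   "et": ets})
            met = gxe.METDataset(values=Y, trials=trials, noise_free=False)
            kin = predict.Kinship(matrix=A)
            fit = predict.fit_etmean(met, kin, np.arange(2), np.array(["ET1", "ET2"]))
            S = fit.fitted["Sigma_E"]
            d = np.sqrt(np.diag(S))
            corr = S / np.outer(d, d)
            errs.append(np.abs(corr - C).max())
        assert np.mean(errs) < 0.15

    def test_single_et_rejected(self):
        met = _simple_met()
        met.trials["et"] = "ET1"
        kin = predict.Kinship(matrix=np.eye(met.n_geno))
        with pytest.raises(ValueError):
            predict.fit_etmean(met, kin, np.array([0]), np.array(["ET1"]))


class TestKinshipPCs:
    def test_identical_trials_identical_coordinates(self):
        rng = np.random.default_rng(2)
        covs = pd.DataFrame(rng.normal(0, 1, (10, 6)),
                            columns=[f"c{i}" for i in range(6)])
        covs.iloc[5] = covs.iloc[4]
        D, Z = predict.env_kinship(covs)
        pcs = predict.env_pcs(D, 3)
        assert np.allclose(pcs[4], pcs[5], atol=1e-8)

    def test_pcs_match_direct_eigendecomposition(self):
        rng = np.random.default_rng(3)
        M = rng.normal(0, 1, (12, 12))
        M = M @ M.T
        pcs = predict.env_pcs(M, 3)
        vals, vecs = np.linalg.eigh(M)
        order = np.argsort(vals)[::-1][:3]
        expected = vecs[:, order] * np.sqrt(vals[order])
        for k in range(3):  # sign-free comparison
            assert (np.allclose(pcs[:, k], expected[:, k], atol=1e-8)
                    or np.allclose(pcs[:, k], -expected[:, k], atol=1e-8))

    def test_twelve_product_vectors(self, e2e):
        D, _ = predict.env_kinship(e2e["covariables"])
        gp = predict.geno_pcs(e2e["kinship"], 4)
        ep = predict.env_pcs(D, 3)
        prod = predict.cross_products(gp, ep)
        assert prod.shape == (80, 40, 12)

    def test_constant_covariable_dropped(self):
        covs = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0],
                             "b": [0.0, 1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            _, Z = predict.env_kinship(covs)
        assert list(Z.columns) == ["b"]


class TestPCModels:
    def test_meanpc_nested_in_indivpc(self):
        """IndivPC with all slopes tied equals MeanPC (x12 covariate scale)."""
        met = _simple_met(n_geno=30, n_trial=8, seed=7)
        rng = np.random.default_rng(8)
        products = rng.normal(0, 1, (30, 8, 12))
        tr = np.arange(6)
        va = np.array([6, 7])
        va_et = met.trials["et"].to_numpy()[va]
        mean_fit = predict.fit_meanpc(met_sub(met, tr), products, tr, va, va_et)
        # tied-slope design: regress on the summed sheets, slope_sum = beta/12
        tied = products.sum(axis=2, keepdims=True)
        tied_fit = predict._fit_fixed_reaction_norm(
            met_sub(met, tr), tied, tr, va, va_et, "tied")
        assert np.allclose(mean_fit.predictions, tied_fit.predictions,
                           atol=1e-8)
        # summed sheets carry 12x the covariate, so the tied slope is 1/12
        assert tied_fit.fitted["slopes"][0] * 12 == pytest.approx(
            mean_fit.fitted["slopes"][0], rel=1e-6)

    def test_indivpc_training_r2_at_least_meanpc(self, e2e):
        meta = e2e["meta"]
        noisy = predict.add_noise(e2e["met"], 0.5, seed=31)
        plan = predict.make_training_plan(meta, n_splits=1, per_et=2, seed=32)
        tr, va = plan.splits[0]["train"], plan.splits[0]["valid"]
        D, _ = predict.env_kinship(e2e["covariables"])
        products = predict.cross_products(predict.geno_pcs(e2e["kinship"], 4),
                                          predict.env_pcs(D, 3))
        train = gxe.METDataset(values=noisy.noisy.values[:, tr],
                               trials=meta.iloc[tr].reset_index(drop=True),
                               noise_free=False)
        va_et = meta["et"].to_numpy()[va]
        m = predict.fit_meanpc(train, products, tr, va, va_et)
        i = predict.fit_indivpc(train, products, tr, va, va_et)
        y = train.values.reshape(-1, order="F")

        def train_r2(fit, sheets):
            n_train = train.n_trial
            td = np.kron(np.eye(n_train), np.ones((train.n_geno, 1)))
            X = np.column_stack(
                [td] + [sheets[:, tr, k].reshape(-1, order="F")
                        for k in range(sheets.shape[2])])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return 1 - r @ r / ((y - y.mean()) @ (y - y.mean()))

        r2_mean = train_r2(m, products.mean(axis=2, keepdims=True))
        r2_indiv = train_r2(i, products)
        assert r2_indiv >= r2_mean - 1e-12

    def test_zero_environmental_variation_zero_slopes(self):
        met = _simple_met(n_geno=25, n_trial=8, seed=9)
        products = np.zeros((25, 8, 12))
        tr, va = np.arange(6), np.array([6, 7])
        va_et = met.trials["et"].to_numpy()[va]
        fit = predict.fit_indivpc(met_sub(met, tr), products, tr, va, va_et)
        assert np.allclose(fit.fitted["slopes"], 0.0)


def met_sub(met, cols):
    return gxe.METDataset(values=met.values[:, cols],
                          trials=met.trials.iloc[cols].reset_index(drop=True),
                          noise_free=False)


class TestFReg:
    def test_recovers_planted_product_term(self):
        hits = 0
        for s in range(10):
            met, params, covs = fixture_generator("freg_toy", seed=40 + s)
            tr = np.arange(16)
            va = np.arange(16, 24)
            va_et = met.trials["et"].to_numpy()[va]
            fit = predict.fit_freg(met_sub(met, tr), params, covs, tr, va,
                                   va_et, alpha=0.01)
            if fit.fitted["terms"] and fit.fitted["terms"][0].startswith("y_rue.sd_P3"):
                hits += 1
        assert hits >= 9

    def test_alpha_zero_gives_empty_model(self):
        met, params, covs = fixture_generator("freg_toy", seed=50)
        tr, va = np.arange(16), np.arange(16, 24)
        va_et = met.trials["et"].to_numpy()[va]
        fit = predict.fit_freg(met_sub(met, tr), params, covs, tr, va, va_et,
                               alpha=0.0)
        assert fit.fitted["terms"] == []
        assert fit.fitted["empty"]

    def test_term_names_use_parameter_dot_covariable(self):
        met, params, covs = fixture_generator("freg_toy", seed=41)
        tr, va = np.arange(16), np.arange(16, 24)
        va_et = met.trials["et"].to_numpy()[va]
        fit = predict.fit_freg(met_sub(met, tr), params, covs, tr, va, va_et)
        for term in fit.fitted["terms"]:
            base = term.replace("^2", "")
            pname, cname = base.split(".", 1)
            assert pname in params.columns
            assert cname in covs.columns


class TestAccuracy:
    def test_fisher_z_round_trip(self):
        for r in (-0.9, 0.0, 0.5):
            assert predict.inverse_fisher_z(predict.fisher_z(r)) == \
                pytest.approx(r, abs=1e-12)

    def test_perfect_predictions_report_one(self):
        truth = _simple_met(seed=3)
        res = predict.PredictionModelResult(
            model="M", predictions=truth.values[:, :4],
            valid_trials=np.arange(4))
        acc = predict.trial_accuracies(res, truth, split=0)
        assert np.allclose(acc["r"], 1.0)

    def test_aggregation_on_z_scale(self):
        df = pd.DataFrame({
            "split": [0, 0, 1, 1], "trial": list("abab"),
            "model": ["M"] * 4, "r": [0.2, 0.4, 0.3, 0.5],
        })
        rep = predict.accuracy(df)
        z = np.arctanh([0.2, 0.4, 0.3, 0.5])
        expected = np.tanh(np.mean([z[:2].mean(), z[2:].mean()]))
        assert rep.summary["mean_r"].iloc[0] == pytest.approx(expected)

    def test_zero_variance_predictions_recorded_missing(self):
        truth = _simple_met(seed=4)
        res = predict.PredictionModelResult(
            model="M", predictions=np.zeros((truth.n_geno, 2)),
            valid_trials=np.arange(2))
        acc = predict.trial_accuracies(res, truth, split=0)
        assert acc["r"].isna().all()


class TestEndToEndOrdering:
    def test_all_models_positive_and_etmean_leads(self, e2e):
        """Directional property: mean accuracy > 0 for all four models and
        the ET-mean model at least matches the averaged-PC model."""
        meta = e2e["meta"]
        noisy = predict.add_noise(e2e["met"], 0.5, seed=61)
        plan = predict.make_training_plan(meta, n_splits=20, per_et=2, seed=62)
        D, _ = predict.env_kinship(e2e["covariables"])
        products = predict.cross_products(
            predict.geno_pcs(e2e["kinship"], 4), predict.env_pcs(D, 3))
        pn = predict.add_noise(
            gxe.METDataset(values=e2e["params"].values,
                           trials=pd.DataFrame(
                               {"trial": list(e2e["params"].spec.names)})),
            0.7, seed=63)
        pphen = pd.DataFrame(pn.noisy.values,
                             columns=list(e2e["params"].spec.names))
        accs = []
        for s, split in enumerate(plan.splits):
            tr, va = split["train"], split["valid"]
            train = gxe.METDataset(values=noisy.noisy.values[:, tr],
                                   trials=meta.iloc[tr].reset_index(drop=True),
                                   noise_free=False)
            va_et = meta["et"].to_numpy()[va]
            fits = [
                predict.fit_etmean(train, e2e["kinship"], va, va_et),
                predict.fit_meanpc(train, products, tr, va, va_et),
                predict.fit_indivpc(train, products, tr, va, va_et),
                predict.fit_freg(train, pphen, e2e["covariables"], tr, va,
                                 va_et, alpha=0.01),
            ]
            for f in fits:
                accs.append(predict.trial_accuracies(f, e2e["met"], split=s))
        rep = predict.accuracy(accs)
        summary = rep.summary.set_index("model")["mean_r"]
        assert (summary > 0).all(), summary
        assert summary["ETmean"] >= summary["MeanPC"]
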