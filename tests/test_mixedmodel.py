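import numpy as np
import pandas as pd
import pytest

from borealgrowth.mixedmodel import (
    LOG2PI,
    MixedModelError,
    MixedModelSpec,
    extract_random_effects,
    fit_reml,
    loglik_reml,
    posthoc_correlation,
    predict_indices,
)
from borealgrowth.synthetic import (
    SyntheticConfig,
    TABLE_TRUTH_FIXED,
    TABLE_TRUTH_SPEC,
    gen_ring_panel,
)
from conftest import dense_reml_loglik

SPEC = MixedModelSpec(
    sd_site=np.array([0.5, 4.0, 2.0e-4]),
    sd_tree=np.array([0.1, 3.0, 1.0e-6]),
    phi=0.8,
    sigma=0.35,
)


class TestRestrictedLikelihood:
    def test_matches_dense_oracle_to_eight_decimals(self, tiny_panel):
        fast = loglik_reml(SPEC, tiny_panel)
        dense = dense_reml_loglik(SPEC, tiny_panel)
        assert fast == pytest.approx(dense, abs=1e-8)

    def test_matches_dense_oracle_with_year_gaps(self, tiny_panel):
        # drop scattered years: the AR(1) correlation must bridge as phi^gap
        panel = tiny_panel.drop(tiny_panel.index[[3, 4, 17, 40, 41, 42, 66]]).reset_index(drop=True)
        fast = loglik_reml(SPEC, panel)
        dense = dense_reml_loglik(SPEC, panel)
        assert fast == pytest.approx(dense, abs=1e-8)

    def test_zero_variances_reduce_to_ols_restricted_likelihood(self, tiny_panel):
        sigma = 0.4
        spec0 = MixedModelSpec(sd_site=np.zeros(3), sd_tree=np.zeros(3), phi=0.0, sigma=sigma)
        got = loglik_reml(spec0, tiny_panel)
        X = np.column_stack([np.ones(len(tiny_panel)), tiny_panel["gpp"], tiny_panel["drought"]])
        y = tiny_panel["index"].to_numpy(float)
        n = len(y)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        _, ld = np.linalg.slogdet(X.T @ X / sigma**2)
        want = -0.5 * (n * np.log(sigma**2) + ld + rss / sigma**2 + (n - 3) * LOG2PI)
        assert got == pytest.approx(want, abs=1e-6)

    def test_invariant_to_site_relabelling(self, tiny_panel):
        base = loglik_reml(SPEC, tiny_panel)
        relabeled = tiny_panel.copy()
        relabeled["site_id"] = relabeled["site_id"].map({"S01": "Z9", "S02": "A0"})
        assert loglik_reml(SPEC, relabeled) == pytest.approx(base, abs=1e-10)

    def test_degenerate_inputs_rejected(self, tiny_panel):
        with pytest.raises(MixedModelError):
            MixedModelSpec(phi=1.0)
        dup = pd.concat([tiny_panel, tiny_panel.iloc[[0]]], ignore_index=True)
        with pytest.raises(MixedModelError):
            loglik_reml(SPEC, dup)


class TestFit:
    def test_recovers_generating_parameters(self, small_recovery_fit):
        _, _, fit = small_recovery_fit
        assert fit.converged
        est = fit.fixed.set_index("term")
        for term, truth in TABLE_TRUTH_FIXED.items():
            z = (est.loc[term, "estimate"] - truth) / est.loc[term, "se"]
            assert abs(z) < 2.0, f"{term} off by {z:.2f} SEs"
        assert fit.phi == pytest.approx(TABLE_TRUTH_SPEC.phi, abs=0.05)
        assert fit.sigma == pytest.approx(TABLE_TRUTH_SPEC.sigma, rel=0.15)

    def test_aic_consistent_with_loglik(self, small_recovery_fit):
        _, _, fit = small_recovery_fit
        assert fit.aic == pytest.approx(2 * 11 - 2 * fit.loglik)

    def test_null_heterogeneity_estimated_near_zero(self):
        cfg = SyntheticConfig(n_sites=6, trees_per_site=4, year_start=1981, year_end=2010, seed=17)
        cfg.truth = MixedModelSpec(
            sd_site=np.zeros(3), sd_tree=np.zeros(3), phi=0.5, sigma=0.3
        )
        panel = gen_ring_panel(cfg)
        fit = fit_reml(panel, seed=17)
        # site-level intercept SD collapses toward the boundary
        assert fit.sd_site[0] < 0.05

    def test_ar_coefficient_recovered_without_random_effects(self):
        cfg = SyntheticConfig(n_sites=2, trees_per_site=2, year_start=1886, year_end=2010, seed=23)
        cfg.truth = MixedModelSpec(sd_site=np.zeros(3), sd_tree=np.zeros(3), phi=0.8, sigma=0.4)
        panel = gen_ring_panel(cfg)  # 4 trees × 125 years = 500 obs
        fit = fit_reml(panel, seed=23)
        assert 0.72 <= fit.phi <= 0.88

    def test_shift_invariance_moves_only_intercept(self):
        cfg = SyntheticConfig(n_sites=5, trees_per_site=3, year_start=1991, year_end=2010, seed=29)
        panel = gen_ring_panel(cfg)
        fit0 = fit_reml(panel, seed=29, n_starts=1)
        shifted = panel.assign(index=panel["index"] + 5.0)
        fit1 = fit_reml(shifted, seed=29, n_starts=1)
        est0 = fit0.fixed.set_index("term")["estimate"]
        est1 = fit1.fixed.set_index("term")["estimate"]
        assert est1["intercept"] - est0["intercept"] == pytest.approx(5.0, abs=1e-3)
        assert est1["gpp"] == pytest.approx(est0["gpp"], abs=1e-3)
        assert est1["drought"] == pytest.approx(est0["drought"], abs=5e-8)
        assert fit1.phi == pytest.approx(fit0.phi, abs=1e-3)

    def test_identifiability_preconditions(self, tiny_panel):
        one_site = tiny_panel[tiny_panel["site_id"] == "S01"]
        with pytest.raises(MixedModelError, match="2 sites"):
            fit_reml(one_site)

    def test_recovery_calibration_over_replicates(self):
        """Repeated-draw check: unbiasedness and near-nominal interval coverage."""
        cfg = SyntheticConfig(n_sites=8, trees_per_site=4, year_start=1981, year_end=2010)
        zs = {t: [] for t in TABLE_TRUTH_FIXED}
        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            panel = gen_ring_panel(cfg, seed=1000 + rep)
            fit = fit_reml(panel, seed=rep, n_starts=1)
            est = fit.fixed.set_index("term")
            for term, truth in TABLE_TRUTH_FIXED.items():
                z = (est.loc[term, "estimate"] - truth) / est.loc[term, "se"]
                zs[term].append(z)
                if abs(z) < 1.96:
                    covered += 1
        for term, zvals in zs.items():
            mean_z = np.mean(zvals)
            # mean estimate within 3 Monte-Carlo SEs of truth
            assert abs(mean_z) < 3.0 / np.sqrt(n_rep), f"{term}: mean z {mean_z:.2f}"
        coverage = covered / (n_rep * 3)
        assert 0.85 <= coverage <= 1.0


class TestPredictionsAndBlups:
    def test_population_prediction_is_linear_form(self, small_recovery_fit):
        _, panel, fit = small_recovery_fit
        pred = predict_indices(fit, panel, conditional=False)
        beta = fit.fixed["estimate"].to_numpy()
        sorted_panel = panel.sort_values(["site_id", "tree_id", "year"]).reset_index(drop=True)
        Xs = np.column_stack([np.ones(len(sorted_panel)), sorted_panel["gpp"], sorted_panel["drought"]])
        assert np.allclose(pred["fitted"], Xs @ beta)

    def test_blup_conditioning_centers_tree_residuals(self, small_recovery_fit):
        _, panel, fit = small_recovery_fit
        cond = predict_indices(fit, panel, conditional=True)
        pop = predict_indices(fit, panel, conditional=False)
        merged = panel.merge(cond, on=["site_id", "tree_id", "year"]).merge(
            pop, on=["site_id", "tree_id", "year"], suffixes=("", "_pop")
        )
        per_tree_cond = (merged["index"] - merged["fitted"]).groupby(merged["tree_id"]).mean()
        per_tree_pop = (merged["index"] - merged["fitted_pop"]).groupby(merged["tree_id"]).mean()
        # conditioning on the BLUPs re-centers each tree; the persistent AR(1)
        # error keeps the means from being exactly zero
        assert np.abs(per_tree_cond).mean() < 0.5 * np.abs(per_tree_pop).mean()
        assert np.abs(per_tree_cond).max() < 0.5

    def test_fitted_track_signal(self, small_recovery_fit):
        _, panel, fit = small_recovery_fit
        pred = predict_indices(fit, panel, conditional=True)
        merged = panel.merge(pred, on=["site_id", "tree_id", "year"])
        r = np.corrcoef(merged["index"], merged["fitted"])[0, 1]
        assert r > 0.9

    def test_unknown_tree_flagged_population_only(self, small_recovery_fit):
        _, panel, fit = small_recovery_fit
        alien = panel.iloc[[0]].assign(site_id="NEW", tree_id="NEWT")
        pred = predict_indices(fit, alien, conditional=True)
        assert bool(pred["population_only"].iloc[0])

    def test_blups_center_near_zero(self, small_recovery_fit):
        _, _, fit = small_recovery_fit
        site, tree = extract_random_effects(fit)
        for term in ("intercept", "gpp"):
            assert abs(site[term].mean()) < 2 * site[term].std() / np.sqrt(len(site)) + 1e-9
            assert abs(tree[term].mean()) < 2 * tree[term].std() / np.sqrt(len(tree)) + 1e-9

    def test_blups_shrink_relative_to_per_tree_ols(self, small_recovery_fit):
        _, panel, fit = small_recovery_fit
        beta = fit.fixed["estimate"].to_numpy()
        _, tree_blups = extract_random_effects(fit)
        devs = []
        for (site, tree), grp in panel.groupby(["site_id", "tree_id"]):
            X = np.column_stack([np.ones(len(grp)), grp["gpp"], grp["drought"]])
            b_ols, *_ = np.linalg.lstsq(X, grp["index"].to_numpy(float), rcond=None)
            devs.append(b_ols - beta)
        devs = np.abs(np.array(devs))
        blups = np.abs(tree_blups[["intercept", "gpp", "drought"]].to_numpy())
        # empirical-Bayes shrinkage: BLUPs are smaller on average, term by term
        # (per-tree OLS deviations also absorb the site effects, so the margin is wide)
        assert np.all(blups.mean(axis=0) < devs.mean(axis=0))

    def test_amplified_tree_ranks_high(self):
        cfg = SyntheticConfig(n_sites=4, trees_per_site=8, year_start=1981, year_end=2010, seed=31)
        panel = gen_ring_panel(cfg)
        # amplify one tree's GPP response far beyond the population spread
        target = panel["tree_id"] == "S01T01"
        panel.loc[target, "index"] += 25.0 * panel.loc[target, "gpp"]
        fit = fit_reml(panel, seed=31, n_starts=1)
        tree = fit.blups_tree.set_index("tree_id")["gpp"]
        rank = tree.rank(pct=True)["S01T01"]
        assert rank > 0.9


class TestPosthoc:
    def test_self_correlation_is_one(self, small_recovery_fit):
        _, _, fit = small_recovery_fit
        r, p, scatter = posthoc_correlation(fit.blups_tree, "gpp", fit.blups_tree["gpp"])
        assert r == pytest.approx(1.0)
        assert len(scatter) == len(fit.blups_tree)

    def test_height_proportional_response_detected(self):
        # a GPP random slope proportional to relative height must show up as a
        # positive, significant post-hoc correlation (asymmetric competition)
        rng = np.random.default_rng(37)
        rel_height = rng.uniform(0.3, 1.0, 200)
        blup_gpp = 3.0 * (rel_height - rel_height.mean()) + rng.normal(0, 0.4, 200)
        blups = pd.DataFrame({"tree_id": [f"t{i}" for i in range(200)], "gpp": blup_gpp})
        r, p, _ = posthoc_correlation(blups, "gpp", rel_height)
        assert r > 0
        assert p < 0.05

    def test_independent_covariate_uniform_p(self):
        rng = np.random.default_rng(41)
        pvals = []
        for _ in range(40):
            blups = pd.DataFrame({"gpp": rng.normal(0, 1, 50)})
            cov = rng.normal(0, 1, 50)
            r, p, _ = posthoc_correlation(blups, "gpp", cov)
            pvals.append(p)
        assert np.mean(np.array(pvals) < 0.5) == pytest.approx(0.5, abs=0.25)
        assert min(pvals) > 1e-6  # no spurious certainty

    def test_zero_variance_covariate_rejected(self, small_recovery_fit):
        _, _, fit = small_recovery_fit
        with pytest.raises(MixedModelError, match="zero-variance"):
            posthoc_correlation(fit.blups_tree, "gpp", np.ones(len(fit.blups_tree)))
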