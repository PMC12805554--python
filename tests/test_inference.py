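import numpy as np
import pandas as pd
import pytest

from spatialproxy import (FitConfig, PosteriorDraws, RegionTable, ate_summary,
                          encode_treatment, fit, make_bases, make_grid_cities,
                          scenario_preset, simulate, split_rhat, waic)


def _fit_cfg(**kw):
    kw.setdefault("n_burn", 500)
    kw.setdefault("n_keep", 500)
    kw.setdefault("thin", 1)
    kw.setdefault("seed", 0)
    return FitConfig(**kw)


def _draws_obj(theta, loglik=None, effect="constant"):
    theta = np.atleast_2d(np.asarray(theta, dtype=float).reshape(-1, 1))
    ll = loglik if loglik is not None else np.zeros((theta.shape[0], 1))
    return PosteriorDraws(draws={"theta": theta}, loglik=np.asarray(ll, dtype=float),
                          waic=0.0, config=_fit_cfg(), effect_names=("treated",),
                          cities=[1])


class TestWaic:
    def test_zero_variance_draws(self):
        ll = np.tile(np.log([0.2, 0.5]), (3, 1))
        assert waic(ll) == pytest.approx(-2 * np.sum(np.log([0.2, 0.5])))

    def test_single_region_reduction(self):
        ll = np.array([[-1.0], [-2.0], [-1.5]])
        from scipy.special import logsumexp
        lppd = logsumexp(ll[:, 0]) - np.log(3)
        p = np.var(ll[:, 0], ddof=1)
        assert waic(ll) == pytest.approx(-2 * (lppd - p))

    def test_needs_two_draws(self):
        with pytest.raises(ValueError, match="2 draws"):
            waic(np.zeros((1, 5)))


class TestAteSummary:
    def test_mean_of_three(self):
        s = ate_summary(_draws_obj([1.0, 2.0, 3.0]))["treated"]
        assert s["mean"] == pytest.approx(2.0)

    def test_symmetric_ci(self):
        x = np.concatenate([np.linspace(-1, 1, 1001)])
        s = ate_summary(_draws_obj(x))["treated"]
        assert s["ci_low"] == pytest.approx(-s["ci_high"], abs=1e-9)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(8)
        s = ate_summary(_draws_obj(rng.normal(0.87, 0.1, size=10_000)))["treated"]
        assert s["ci_low"] == pytest.approx(0.87 - 1.96 * 0.1, abs=0.02)
        assert s["ci_high"] == pytest.approx(0.87 + 1.96 * 0.1, abs=0.02)


class TestConjugateToyOracle:
    def test_theta_posterior_matches_closed_form(self, tiny_table):
        # fix alpha_y and sigma2_y: theta | data is exactly N(m, v) with
        # v = 1/(sum a^2 / s2 + 1/c2), m = v * sum a y / s2
        cfg = _fit_cfg(variant="no_adjustment", r=0.0, n_burn=500, n_keep=4000,
                       fixed={"alpha_y": 0.0, "sigma2_y": 1.0})
        design = encode_treatment(tiny_table, "binary")
        draws = fit(tiny_table, None, design, cfg)
        a = design.matrix[:, 0]
        y = tiny_table.outcome()
        v = 1.0 / (a @ a / 1.0 + 1.0 / 100.0)
        m = v * (a @ y)
        th = draws.draws["theta"][:, 0]
        mcse = th.std(ddof=1) / np.sqrt(len(th) / 10)  # conservative ESS guess
        assert th.mean() == pytest.approx(m, abs=3 * mcse)
        assert th.std(ddof=1) == pytest.approx(np.sqrt(v), rel=0.1)

    def test_fixed_theta_stays_fixed(self, tiny_table):
        cfg = _fit_cfg(variant="no_adjustment", r=0.0, fixed={"theta": 0.33})
        draws = fit(tiny_table, None, encode_treatment(tiny_table, "binary"), cfg)
        assert np.all(draws.draws["theta"] == 0.33)


class TestVariantBehaviour:
    def test_no_adjustment_badly_biased_under_confounding(self):
        cfg = scenario_preset("strong_confounding")
        geo = make_grid_cities(10, 7)
        data = simulate(cfg, geo, seed=21)
        design = encode_treatment(data.table, "binary")
        bases = data.bases  # r_true = 0.4
        draws = fit(data.table, bases, design,
                    _fit_cfg(variant="no_adjustment", r=0.4, n_burn=800, n_keep=800))
        s = ate_summary(draws)["treated"]
        assert abs(s["mean"] - 1.0) > 5 * s["sd"]

    def test_no_confounding_all_variants_agree(self):
        cfg = scenario_preset("base").replace(
            n_cities=2, grid_dim=5, alpha_yu=[0.0], alpha_au=[0.0],
            alpha_az=0.0, alpha_yz=0.0, sigma2_z=0.0)
        geo = make_grid_cities(2, 5)
        data = simulate(cfg, geo, seed=17)
        design = encode_treatment(data.table, "binary")
        means, sds = {}, {}
        for v in ("latent_adjustment", "outcome_regression_proxy", "no_adjustment"):
            d = fit(data.table, None, design,
                    _fit_cfg(variant=v, r=0.0, n_burn=1500, n_keep=3000))
            s = ate_summary(d)["treated"]
            means[v], sds[v] = s["mean"], s["sd"]
        spread = max(means.values()) - min(means.values())
        assert spread < 2.0 * max(sds.values())

    def test_rotation_invariance_q2(self):
        cfg = scenario_preset("base").replace(
            n_cities=2, grid_dim=5, q=2, p=5,
            alpha_yu=[0.8, 0.5], alpha_au=[0.7, -0.4],
            alpha_wu=np.array([[1.0, 0.2], [0.6, 0.9], [0.8, -0.5],
                               [0.3, 0.7], [0.9, 0.4]]),
            alpha_w=np.zeros(5), alpha_yz=0.0, alpha_az=0.0,
            sigma2_z=0.0, sigma2_w=0.5)
        geo = make_grid_cities(2, 5)
        data = simulate(cfg, geo, seed=9)
        design = encode_treatment(data.table, "binary")
        stats = []
        for seed in (1, 2):
            d = fit(data.table, None, design,
                    _fit_cfg(variant="latent_adjustment", q=2, r=0.0,
                             n_burn=2000, n_keep=4000, seed=seed))
            s = ate_summary(d)["treated"]
            stats.append(s)
            # sign constraint pins the loading orientation
            assert np.all(d.draws["alpha_wu"][:, 0, :] > 0)
        mcse = max(s["sd"] for s in stats) / np.sqrt(4000 / 20)
        assert stats[0]["mean"] == pytest.approx(stats[1]["mean"], abs=4 * mcse)

    def test_latent_recovers_truth_single_fit(self, base_dataset):
        design = encode_treatment(base_dataset.table, "binary")
        d = fit(base_dataset.table, base_dataset.bases, design,
                _fit_cfg(variant="latent_adjustment", r=0.4, n_burn=1500, n_keep=1500))
        s = ate_summary(d)["treated"]
        assert abs(s["mean"] - 1.0) < 0.35


class TestMultilevel:
    def test_recovers_graded_effects(self):
        from spatialproxy import simulate_multilevel
        cfg = scenario_preset("base").replace(theta=[0.5, 1.0, 1.5])
        geo = make_grid_cities(10, 7)
        data = simulate_multilevel(cfg, geo, seed=31)
        design = encode_treatment(data.table, "multilevel")
        d = fit(data.table, data.bases, design,
                _fit_cfg(variant="latent_adjustment", r=0.4,
                         n_burn=1200, n_keep=1200))
        s = ate_summary(d)
        assert abs(s["B"]["mean"] - 0.5) < 0.4
        assert abs(s["C"]["mean"] - 1.0) < 0.4
        assert abs(s["D"]["mean"] - 1.5) < 0.4
        # per-treatment spatial coefficients are sampled separately
        assert d.draws["alpha_az"].shape[1] == 3


class TestRandomEffects:
    def test_random_effect_fit_structure(self):
        cfg = scenario_preset("base").replace(n_cities=4, grid_dim=5, effect_sd=0.4)
        geo = make_grid_cities(4, 5)
        data = simulate(cfg, geo, seed=6)
        design = encode_treatment(data.table, "binary")
        d = fit(data.table, data.bases, design,
                _fit_cfg(variant="latent_adjustment", effect="random", r=0.4,
                         n_burn=800, n_keep=800))
        assert d.draws["theta_city"].shape == (800, 4, 1)
        assert np.all(d.draws["tau"] > 0)
        s = ate_summary(d)
        assert "cities" in s and len(s["cities"]) == 4
        assert abs(s["treated"]["mean"] - 1.0) < 0.8


class TestValidation:
    def test_all_treated_is_singular(self, tiny_table):
        df = tiny_table.df.copy()
        df["treatment"] = 1
        t = RegionTable(df)
        with pytest.raises(ValueError, match="singular design"):
            fit(t, None, encode_treatment(t, "binary"), _fit_cfg(variant="no_adjustment", r=0.0))

    def test_ratio_mismatch_rejected(self, small_dataset):
        design = encode_treatment(small_dataset.table, "binary")
        bases = make_bases(small_dataset.table, 0.2)
        with pytest.raises(ValueError, match="ratio"):
            fit(small_dataset.table, bases, design, _fit_cfg(r=0.4))

    def test_missing_bases_rejected(self, small_dataset):
        design = encode_treatment(small_dataset.table, "binary")
        with pytest.raises(ValueError, match="basis"):
            fit(small_dataset.table, None, design, _fit_cfg(r=0.4))

    def test_retained_draw_count(self, tiny_table):
        cfg = _fit_cfg(variant="no_adjustment", r=0.0, n_burn=50, n_keep=90, thin=7)
        d = fit(tiny_table, None, encode_treatment(tiny_table, "binary"), cfg)
        assert d.n_draws == 90 // 7

    def test_proxy_variant_needs_proxies(self):
        df = pd.DataFrame({"city": [1, 1], "region": [1, 2], "outcome": [0.1, 0.2],
                           "treatment": [0, 1]})
        t = RegionTable(df)
        with pytest.raises(ValueError, match="proxy"):
            fit(t, None, encode_treatment(t, "binary"),
                _fit_cfg(variant="outcome_regression_proxy", r=0.0))


def test_split_rhat_iid_chain():
    rng = np.random.default_rng(0)
    assert split_rhat(rng.normal(size=4000)) < 1.05


def test_rhat_detects_divergent_chains():
    from spatialproxy import rhat
    rng = np.random.default_rng(1)
    good = rhat(rng.normal(size=(2, 2000)))
    bad = rhat(np.stack([rng.normal(size=2000), rng.normal(5.0, 1.0, size=2000)]))
    assert good < 1.05 < bad


def test_plot_trace_writes_file(tiny_table, tmp_path):
    from spatialproxy import plot_trace
    d = fit(tiny_table, None, encode_treatment(tiny_table, "binary"),
            _fit_cfg(variant="no_adjustment", r=0.0))
    f = tmp_path / "trace.png"
    plot_trace(d, f)
    assert f.stat().st_size > 0


def test_diagnostics_attached(tiny_table):
    d = fit(tiny_table, None, encode_treatment(tiny_table, "binary"),
            _fit_cfg(variant="no_adjustment", r=0.0))
    assert "split_rhat_theta" in d.diagnostics
    assert d.diagnostics["split_rhat_theta"][0] < 1.2
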