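"""Monte-Carlo engine: data generation, truncation accounting, grid runner."""

import math
import textwrap

import numpy as np
import pandas as pd
import pytest

from lrrmeta import (
    PopulationArm,
    SimulationConfig,
    evaluate_cell,
    generate_lognormal_meta,
    generate_normal_meta,
    load_grid,
    prob_undefined,
    run_grid,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"distribution": "weibull"},
            {"distribution": "normal", "tau2": -0.1},
            {"distribution": "normal", "n": 5},
            {"distribution": "normal", "n": 2},
            {"distribution": "normal", "k": 1},
            {"distribution": "normal", "reps": 0},
        ],
    )
    def test_rejects_bad_configs(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestNormalGeneration:
    def test_no_truncation_for_large_means(self):
        cfg = SimulationConfig("normal", mu_c=1e6, k=8, n=10, reps=1)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert generate_normal_meta(cfg, rng).k == 8

    def test_retention_matches_analytic_probability(self):
        """At (lambda=0, tau2=0, mu_C=1, n=4) the per-study retention rate
        must match 1 - prob_undefined within binomial Monte-Carlo error."""
        cfg = SimulationConfig("normal", lam=0.0, tau2=0.0, mu_c=1.0, k=5, n=4, reps=1)
        arm = PopulationArm(mu=1.0, sigma=1.0, n=2)
        p_keep = 1.0 - prob_undefined(arm, arm)
        rng = np.random.default_rng(1)
        total = kept = 0
        for _ in range(3000):
            data = generate_normal_meta(cfg, rng)
            total += cfg.k
            kept += 0 if data is None else data.k
        rate = kept / total
        se = math.sqrt(p_keep * (1 - p_keep) / total)
        assert abs(rate - p_keep) < 3 * se

    def test_summary_moments_match_model_at_large_n(self):
        """tau2 = 0, n = 1000: the effects' mean approaches lambda and
        their spread matches the estimated within-study variances."""
        cfg = SimulationConfig("normal", lam=0.3, tau2=0.0, mu_c=4.0, k=4000, n=1000, reps=1)
        data = generate_normal_meta(cfg, np.random.default_rng(2))
        mean_v = float(np.mean(data.var))
        assert float(np.mean(data.lrr)) == pytest.approx(0.3, abs=3 * math.sqrt(mean_v / data.k))
        assert float(np.var(data.lrr, ddof=1)) == pytest.approx(mean_v, rel=0.1)


class TestLognormalGeneration:
    def test_moment_matched_arms(self):
        """Arm-level raw-scale mean and variance reproduce (mu, sigma2)."""
        cfg = SimulationConfig("lognormal", lam=0.4, tau2=0.0, mu_c=1.0, k=3, n=200000, reps=1)
        data = generate_lognormal_meta(cfg, np.random.default_rng(3))
        for t, c in data.arms:
            assert c.mean == pytest.approx(1.0, abs=0.02)
            assert c.sd == pytest.approx(1.0, abs=0.03)
            assert t.mean == pytest.approx(math.exp(0.4), abs=0.03)

    def test_never_discards(self):
        cfg = SimulationConfig("lognormal", lam=0.0, tau2=1.0, k=10, n=4, reps=1)
        rng = np.random.default_rng(4)
        for _ in range(50):
            assert generate_lognormal_meta(cfg, rng).k == 10


class TestEvaluateCell:
    def test_seed_determinism(self):
        cfg = SimulationConfig("normal", lam=0.2, tau2=0.3, mu_c=4.0, k=5, n=40, reps=50)
        a = evaluate_cell(cfg, np.random.default_rng(10))
        b = evaluate_cell(cfg, np.random.default_rng(10))
        pd.testing.assert_frame_equal(a, b)

    def test_mse_dominates_squared_bias(self):
        cfg = SimulationConfig("normal", lam=0.0, tau2=0.2, mu_c=4.0, k=5, n=40, reps=100)
        res = evaluate_cell(
            cfg, np.random.default_rng(11), tau2_intervals=(), lambda_intervals=()
        )
        pts = res[res.kind.str.endswith("_point")]
        assert (pts.mse >= pts.bias**2 - 1e-12).all()

    def test_tau2_estimators_consistent_at_zero_heterogeneity(self):
        """tau2 = 0, n = 1000, K = 30, mu_C = 4: every tau2 estimator's
        mean collapses toward zero (truncation keeps it slightly positive,
        so the check is an absolute bound a decade above the noise scale)."""
        cfg = SimulationConfig("normal", lam=0.0, tau2=0.0, mu_c=4.0, k=30, n=1000, reps=200)
        res = evaluate_cell(
            cfg, np.random.default_rng(12), tau2_intervals=(), lambda_methods=(), lambda_intervals=()
        )
        assert (res.bias.abs() < 1e-4).all()

    def test_coverage_and_width_columns(self):
        cfg = SimulationConfig("normal", lam=0.0, tau2=0.3, mu_c=4.0, k=5, n=100, reps=40)
        res = evaluate_cell(
            cfg,
            np.random.default_rng(13),
            tau2_methods=("DL", "MP"),
            tau2_intervals=("QP",),
            lambda_methods=("FE", "SSW"),
            lambda_intervals=("HKSJ(MP)", "SSW MP"),
        )
        iv = res[res.kind == "lambda_interval"].set_index("method")
        assert set(iv.index) == {"HKSJ(MP)", "SSW MP"}
        assert ((iv.coverage >= 0) & (iv.coverage <= 1)).all()
        assert (iv.mean_width > 0).all()
        cov = iv.loc["SSW MP", "coverage"]
        n_used = iv.loc["SSW MP", "reps_used"]
        assert iv.loc["SSW MP", "mc_se_coverage"] == pytest.approx(
            math.sqrt(cov * (1 - cov) / n_used)
        )


class TestGrid:
    def test_run_grid_is_reproducible_and_tidy(self):
        cfgs = [
            SimulationConfig("normal", lam=0.0, tau2=t, mu_c=4.0, k=5, n=40, reps=30)
            for t in (0.0, 0.5)
        ]
        a = run_grid(cfgs, seed=99, tau2_intervals=(), lambda_intervals=())
        b = run_grid(cfgs, seed=99, tau2_intervals=(), lambda_intervals=())
        pd.testing.assert_frame_equal(a, b)
        assert set(a.tau2.unique()) == {0.0, 0.5}

    def test_load_grid_expands_factorially(self, tmp_path):
        cfg_file = tmp_path / "grid.yaml"
        cfg_file.write_text(
            textwrap.dedent(
                """
                distribution: normal
                lambda: [0, 0.5]
                tau2: [0, 1]
                mu_c: 1
                K: [5, 10]
                n: 40
                reps: 10000
                """
            )
        )
        configs = load_grid(cfg_file)
        assert len(configs) == 8
        assert {c.reps for c in configs} == {10000}
        assert len(load_grid(cfg_file, reps=50)) == 8
        assert {c.reps for c in load_grid(cfg_file, reps=50)} == {50}

    def test_load_grid_rejects_unknown_keys(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("distribution: normal\nshape: 3\n")
        with pytest.raises(ValueError):
            load_grid(bad)
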