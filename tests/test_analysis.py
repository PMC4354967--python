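"""Pearson correlation machinery and polynomial trend fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nsensor as ns


def pearson_oracle(x, y):
    """Covariance-ratio oracle, coded independently of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = ns.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        r, _ = ns.pearson(x, -x)
        assert r == pytest.approx(-1.0)

    @given(seed=st.integers(min_value=0, max_value=5000))
    def test_matches_covariance_ratio_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, p = ns.pearson(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ns.UndefinedInputError):
            ns.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(seed=st.integers(min_value=0, max_value=5000),
           a=st.floats(min_value=0.1, max_value=10.0),
           b=st.floats(min_value=-5.0, max_value=5.0))
    def test_symmetric_and_affine_invariant(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r_xy, _ = ns.pearson(x, y)
        r_yx, _ = ns.pearson(y, x)
        r_scaled, _ = ns.pearson(a * x + b, y)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert r_xy == pytest.approx(r_scaled, abs=1e-9)


class TestCorrelationTable:
    def test_default_trial_cell_counts(self, default_trial):
        cells = ns.correlation_table(default_trial)
        per_stage = [c for c in cells if c.stage != "overall"]
        overall = [c for c in cells if c.stage == "overall"]
        assert len(per_stage) == 3 * 3 * 3
        assert len(overall) == 3 * 3
        assert all(abs(c.r) <= 1 for c in cells if not c.flagged)
        assert all(c.n == 18 for c in per_stage)
        assert all(c.n == 54 for c in overall)

    def test_noiseless_trial_perfectly_correlated_within_stage(self):
        truth = ns.default_truth().with_noise(
            si_spad=0.0, si_sensor=0.0, sn=0.0, biomass=0.0,
            lab_n=0.0, lab_chl=0.0, sigma_yield=0.0, block_sd=0.0,
        )
        df = ns.simulate_trial(ns.TrialDesign(seed=0), truth)
        cells = ns.correlation_table(df)
        for cell in cells:
            if cell.stage == "overall":
                continue
            assert abs(cell.r) == pytest.approx(1.0, abs=1e-9), cell

    def test_shuffled_rows_give_identical_table(self, default_trial):
        shuffled = default_trial.sample(frac=1.0, random_state=9)
        a = ns.correlation_frame(default_trial)
        b = ns.correlation_frame(shuffled)
        assert np.allclose(a["r"], b["r"], atol=1e-12)

    def test_insufficient_cells_flagged_not_fatal(self, default_trial):
        tiny = default_trial.groupby("stage").head(2)
        cells = ns.correlation_table(tiny)
        assert all(c.flagged for c in cells if c.stage != "overall")
        assert any(not c.flagged for c in cells if c.stage == "overall")

    def test_tillering_predicts_yield_better_than_ear_emergence(self):
        """Sensor-value/yield correlation is strongest at tillering for
        the default noisy generator, in >= 90% of seeds."""
        wins = 0
        n_seeds = 60
        for seed in range(n_seeds):
            df = ns.simulate_trial(ns.TrialDesign(seed=seed))
            till = df[df["stage"] == "tillering"]
            ear = df[df["stage"] == "ear_emergence"]
            r_till, _ = ns.pearson(till["sn"], till["yield_t_ha"])
            r_ear, _ = ns.pearson(ear["sn"], ear["yield_t_ha"])
            wins += r_till > r_ear
        assert wins >= 0.9 * n_seeds


class TestTrendFit:
    def test_exact_quadratic_has_unit_r_squared(self):
        n = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
        y = 0.5 + 0.004 * n - 1.5e-5 * n**2
        coeffs, r2 = ns.trend_fit(n, y)
        assert coeffs == pytest.approx([0.5, 0.004, -1.5e-5], rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_has_zero_r_squared(self):
        n = np.array([0.0, 50.0, 100.0, 150.0])
        _, r2 = ns.trend_fit(n, np.full(4, 2.0))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    @given(seed=st.integers(min_value=0, max_value=5000))
    def test_r_squared_matches_sse_sst_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.uniform(0, 150, size=10)
        y = rng.normal(size=10)
        coeffs, r2 = ns.trend_fit(n, y)
        fitted = sum(c * n**k for k, c in enumerate(coeffs))
        oracle = 1 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(oracle, abs=1e-12)

    @given(seed=st.integers(min_value=0, max_value=5000))
    def test_r_squared_non_decreasing_in_degree(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.uniform(0, 150, size=12)
        y = rng.normal(size=12)
        r2s = [ns.trend_fit(n, y, degree=d)[1] for d in (0, 1, 2, 3)]
        assert all(b >= a - 1e-10 for a, b in zip(r2s, r2s[1:]))

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ns.RankDeficiencyError):
            ns.trend_fit([0.0, 0.0, 150.0], [1.0, 2.0, 3.0], degree=2)
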