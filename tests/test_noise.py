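"""Dual-reporter noise estimators: hand cases, invariants, consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from floralnoise import (
    DualReporterNoise,
    ExpressionModel,
    MeristemGeometry,
    StudyConfig,
    closed_form_noise,
    conditional_noise_map,
    generate_bud,
    generate_cohort,
    intrinsic_noise_by_depth,
    noise_signal_relation,
    pooled_noise,
    register_cohort,
)
from floralnoise.noise import NoiseEstimate, NoiseMap, UndefinedNoiseError, aggregate_noise

from conftest import build_bud


class TestPooledNoise:
    def test_hand_case_anticorrelated(self):
        est = pooled_noise([1, 2], [2, 1])
        assert est.eta2_ext == pytest.approx(-1 / 9, abs=1e-15)
        assert est.eta2_int == pytest.approx(2 / 9, abs=1e-15)
        assert est.eta2_tot == pytest.approx(1 / 9, abs=1e-15)
        assert "eta2_ext_negative" in est.flags
        assert est.eta_ext == 0.0  # clamped before sqrt

    def test_hand_case_correlated(self):
        est = pooled_noise([1, 2], [1, 2])
        assert est.eta2_ext == pytest.approx(1 / 9, abs=1e-15)
        assert est.eta2_int == pytest.approx(0.0, abs=1e-15)

    def test_constant_signal_no_noise(self):
        est = pooled_noise([3, 3, 3], [3, 3, 3])
        assert est.eta2_ext == est.eta2_int == est.eta2_tot == 0.0

    def test_channel_swap_symmetry(self):
        rng = np.random.default_rng(1)
        c1, c2 = rng.uniform(0.5, 5, 30), rng.uniform(0.5, 5, 30)
        a, b = pooled_noise(c1, c2), pooled_noise(c2, c1)
        assert a.eta2_ext == b.eta2_ext
        assert a.eta2_int == b.eta2_int

    def test_joint_scale_invariance(self):
        rng = np.random.default_rng(2)
        c1, c2 = rng.uniform(0.5, 5, 30), rng.uniform(0.5, 5, 30)
        a, b = pooled_noise(c1, c2), pooled_noise(7.3 * c1, 7.3 * c2)
        assert a.eta2_ext == pytest.approx(b.eta2_ext, rel=1e-12)
        assert a.eta2_int == pytest.approx(b.eta2_int, rel=1e-12)

    def test_single_channel_scaling_moves_only_intrinsic(self):
        rng = np.random.default_rng(3)
        c1, c2 = rng.uniform(0.5, 5, 50), rng.uniform(0.5, 5, 50)
        a, b = pooled_noise(c1, c2), pooled_noise(c1, 2.0 * c2)
        assert a.eta2_ext == pytest.approx(b.eta2_ext, rel=1e-12)
        assert a.eta2_int != pytest.approx(b.eta2_int, rel=1e-6)

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedNoiseError):
            pooled_noise([0, 0], [1, 2])

    def test_too_few_cells_rejected(self):
        with pytest.raises(UndefinedNoiseError):
            pooled_noise([1], [1])

    @given(
        n=st.integers(min_value=2, max_value=50),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_additivity_identity(self, n, seed):
        rng = np.random.default_rng(seed)
        c1 = rng.uniform(0.1, 10.0, n)
        c2 = rng.uniform(0.1, 10.0, n)
        est = pooled_noise(c1, c2)
        assert abs(est.eta2_tot - (est.eta2_ext + est.eta2_int)) <= 1e-12

    def test_consistency_against_closed_form(self):
        geo = MeristemGeometry(30.0, 100_000)
        model = ExpressionModel(baseline=100.0, foci=(), patch_rate=0.0,
                                sigma_ext=0.5, sigma_int=0.5, sigma_meas=0.0)
        bud, truth = generate_bud(geo, model, "2c", "b", seed=2)
        est = pooled_noise(bud.signal("c1"), bud.signal("c2"))
        assert est.eta2_ext == pytest.approx(truth.eta2_ext_true, rel=0.02)
        assert est.eta2_int == pytest.approx(truth.eta2_int_true, rel=0.02)


class TestConditionalNoiseMap:
    def make_cohort(self, model, n_buds=6, n_cells=300, stage="2c", seed=0):
        sims = generate_cohort(
            {stage: n_buds}, MeristemGeometry(30.0, n_cells), model, seed=seed
        )
        return register_cohort([b for b, _ in sims])

    def test_conditioning_removes_positional_component(self):
        # deterministic tile-constant pattern, no stochastic noise: pooled
        # extrinsic noise is positive while every tile estimate vanishes
        from floralnoise.simulate import four_sepal_foci

        model = ExpressionModel(
            baseline=5.0, foci=four_sepal_foci(amplitude=100.0, width=0.15),
            patch_rate=0.0, sigma_ext=0.0, sigma_int=0.0,
            quantize_binwidth=0.25,
        )
        cohort = self.make_cohort(model)
        cells = pd.concat([b.data for b in cohort], ignore_index=True)
        pooled = pooled_noise(cells["c1"].to_numpy(), cells["c2"].to_numpy())
        assert pooled.eta2_ext > 0.1
        nmap = conditional_noise_map(cohort, ("c1", "c2"))
        assert nmap.estimates
        for est in nmap.estimates.values():
            assert abs(est.eta2_ext) < 1e-9
            assert est.eta2_int == 0.0

    def test_uniform_field_conditional_matches_pooled(self):
        model = ExpressionModel(baseline=100.0, foci=(), patch_rate=0.0,
                                sigma_ext=0.4, sigma_int=0.3)
        cohort = self.make_cohort(model, n_buds=10, n_cells=2000)
        cells = pd.concat([b.data for b in cohort], ignore_index=True)
        pooled = pooled_noise(cells["c1"].to_numpy(), cells["c2"].to_numpy())
        agg = conditional_noise_map(cohort, ("c1", "c2")).aggregate()
        assert agg.eta2_ext == pytest.approx(pooled.eta2_ext, rel=0.1, abs=0.01)
        assert agg.eta2_int == pytest.approx(pooled.eta2_int, rel=0.05)

    def test_min_cell_rule(self):
        cfg = StudyConfig(min_cells_per_noise_bin=5)
        # two tiles: one with 6 cells, one with 4
        x = [5.0] * 6 + [-5.0] * 4
        y = [0.001 * k for k in range(6)] + [0.001 * k for k in range(4)]
        bud = build_bud(x, y, c1=np.ones(10) * 2, c2=np.ones(10) * 2)
        cohort = register_cohort([bud], cfg)
        nmap = conditional_noise_map(cohort, ("c1", "c2"), cfg)
        assert len(nmap.estimates) == 1
        (est,) = nmap.estimates.values()
        assert est.n_cells == 6

    def test_empty_map_warns(self):
        cfg = StudyConfig(min_cells_per_noise_bin=50)
        bud = build_bud([5.0, 5.0], [0.0, 0.01], c1=[1, 2], c2=[2, 1])
        cohort = register_cohort([bud], cfg)
        with pytest.warns(UserWarning, match="no tile meets"):
            nmap = conditional_noise_map(cohort, ("c1", "c2"), cfg)
        assert nmap.estimates == {}


class TestIntrinsicNoiseByDepth:
    def test_equal_channels_zero_everywhere(self):
        cells = pd.DataFrame({
            "depth_um": np.linspace(0, 9, 40),
            "c1": np.linspace(1, 5, 40),
            "c2": np.linspace(1, 5, 40),
        })
        for est in intrinsic_noise_by_depth(cells, ("c1", "c2")):
            assert est.eta2_int == 0.0
            assert "eta2_ext_biased_expressing_filter" in est.flags

    def test_depth_ordering_recovered_from_simulation(self):
        # shallow cells noisier (sigma_int 0.6) than deep (0.2)
        rng = np.random.default_rng(8)
        n = 10_000
        frames = []
        for depth, sigma in ((1.0, 0.6), (7.0, 0.2)):
            c1 = 50.0 * np.exp(rng.normal(0, sigma, n))
            c2 = 50.0 * np.exp(rng.normal(0, sigma, n))
            frames.append(pd.DataFrame({
                "depth_um": np.full(n, depth), "c1": c1, "c2": c2,
            }))
        cells = pd.concat(frames, ignore_index=True)
        ests = intrinsic_noise_by_depth(cells, ("c1", "c2"))
        assert len(ests) == 2
        shallow, deep = ests[0], ests[-1]
        assert shallow.eta2_int > deep.eta2_int
        for est, sigma in ((shallow, 0.6), (deep, 0.2)):
            _, eta2_int = closed_form_noise(0.0, sigma)
            assert est.eta2_int == pytest.approx(eta2_int, rel=0.1)

    def test_threshold_above_all_signals(self):
        cells = pd.DataFrame({"depth_um": [1.0, 2.0], "c1": [1, 2], "c2": [2, 1]})
        cfg = StudyConfig(expressing_threshold=100.0)
        with pytest.warns(UserWarning, match="no expressing cells"):
            assert intrinsic_noise_by_depth(cells, ("c1", "c2"), cfg) == []


def synthetic_map(etas, signals, stage="2c"):
    estimates = {}
    for k, (eta, sig) in enumerate(zip(etas, signals)):
        estimates[(k, 0)] = NoiseEstimate(
            eta2_ext=eta ** 2, eta2_int=eta ** 2, eta2_tot=2 * eta ** 2,
            eta_ext=eta, eta_int=eta, n_cells=10, key=(k, 0, stage),
            mean_sum_signal=sig, mean_c1=sig / 2, mean_c2=sig / 2,
        )
    return NoiseMap(stage=stage, channels=("c1", "c2"), estimates=estimates)


class TestNoiseSignalRelation:
    def test_exact_linear_fixture(self):
        signals = np.array([1.0, 2.0, 3.0, 4.0])
        etas = 2.0 - 0.25 * signals  # eta = a - b*signal
        table, fits = noise_signal_relation(synthetic_map(etas, signals))
        assert len(table) == 4
        assert fits["eta_ext"]["slope"] == pytest.approx(-0.25)
        assert fits["eta_ext"]["r"] == pytest.approx(-1.0)

    def test_constant_noise_zero_slope(self):
        table, fits = noise_signal_relation(
            synthetic_map([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])
        )
        assert fits["eta_ext"]["slope"] == 0.0
        assert fits["eta_ext"]["r"] == 0.0

    def test_single_tile_no_fit(self):
        table, fits = noise_signal_relation(synthetic_map([0.5], [1.0]))
        assert len(table) == 1 and fits == {}


class TestAggregateNoise:
    def test_single_bin_reduces_to_itself(self):
        est = pooled_noise([1.0, 2.0, 3.0], [2.0, 2.0, 4.0])
        agg = aggregate_noise([est])
        assert agg.eta2_ext == pytest.approx(est.eta2_ext, rel=1e-12)
        assert agg.eta2_int == pytest.approx(est.eta2_int, rel=1e-12)

    def test_weighted_pooling(self):
        a = pooled_noise([1.0, 3.0], [3.0, 1.0])
        b = pooled_noise([10.0, 10.0], [10.0, 10.0])
        agg = aggregate_noise([a, b])
        # high-signal quiet bin dominates the ratio-of-sums
        assert abs(agg.eta2_int) < abs(a.eta2_int)


class TestDualReporterNoiseModel:
    def test_fit_and_summary(self):
        sims = generate_cohort({"2c": 4}, MeristemGeometry(30.0, 200),
                               ExpressionModel.for_stage("2c"), seed=4)
        cohort = register_cohort([b for b, _ in sims])
        model = DualReporterNoise.from_cohort(cohort, ("c1", "c2"))
        res = model.fit(seed=0, n_bootstrap=100)
        text = res.summary()
        assert "pooled extrinsic" in text and "cond. intrinsic" in text
        lo, hi = res.bootstrap_ci["eta2_int"]
        assert lo <= res.pooled.eta2_int <= hi

    def test_fit_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"c1": rng.uniform(1, 5, 50), "c2": rng.uniform(1, 5, 50)})
        model = DualReporterNoise.from_dataframe(df, ("c1", "c2"))
        a = model.fit(seed=3, n_bootstrap=50)
        b = model.fit(seed=3, n_bootstrap=50)
        assert a.bootstrap_ci == b.bootstrap_ci
        assert a.pooled == b.pooled
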