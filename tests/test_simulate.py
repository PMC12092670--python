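"""Synthetic meristem generator: geometry, determinism, noise ground truth."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from floralnoise import (
    ExpressionModel,
    MeristemGeometry,
    apply_perturbation,
    closed_form_noise,
    four_sepal_foci,
    generate_bud,
    generate_cohort,
    pooled_noise,
)
from floralnoise.config import ConfigError
from floralnoise.simulate import ScenarioError, derive_bud_seed


def quiet_model(**kw):
    defaults = dict(foci=(), patch_rate=0.0, sigma_ext=0.0, sigma_int=0.0,
                    sigma_meas=0.0)
    defaults.update(kw)
    return ExpressionModel(**defaults)


class TestGenerateBud:
    def test_noise_free_bud_reproduces_mean_exactly(self):
        model = quiet_model(baseline=10.0, foci=four_sepal_foci())
        geo = MeristemGeometry(30.0, 150)
        bud, _ = generate_bud(geo, model, "2c", "b", seed=1)
        c1, c2 = bud.signal("c1"), bud.signal("c2")
        assert np.array_equal(c1, c2)
        # reconstruct mu from positions
        xn = bud.data["x_um"].to_numpy() / geo.dome_radius
        yn = bud.data["y_um"].to_numpy() / geo.dome_radius
        mu = np.full_like(xn, 10.0)
        for f in model.foci:
            mu += f.amplitude * np.exp(
                -((xn - f.x) ** 2 + (yn - f.y) ** 2) / (2 * f.width ** 2)
            )
        np.testing.assert_allclose(c1, mu, rtol=1e-12)

    def test_same_seed_identical_output(self):
        geo = MeristemGeometry(25.0, 80)
        model = ExpressionModel(patch_rate=2.0)
        a, ta = generate_bud(geo, model, "1a", "b", seed=7)
        b, tb = generate_bud(geo, model, "1a", "b", seed=7)
        assert a.equals(b, rtol=0.0)
        assert ta == tb

    def test_cells_lie_on_upper_dome(self):
        geo = MeristemGeometry(30.0, 200)
        bud, _ = generate_bud(geo, quiet_model(), "2c", "b", seed=3)
        assert bud.n_records == 200
        r2 = (bud.data[["x_um", "y_um", "z_um"]] ** 2).sum(axis=1).to_numpy()
        np.testing.assert_allclose(r2, geo.dome_radius ** 2, rtol=1e-6)
        assert (bud.data["z_um"] >= 0).all()

    def test_invalid_cell_count_rejected(self):
        with pytest.raises(ConfigError):
            MeristemGeometry(30.0, 0)

    def test_placement_uniform_in_height(self):
        # area-uniform sampling on a sphere makes z/R uniform on [0, 1]
        geo = MeristemGeometry(30.0, 10_000)
        bud, _ = generate_bud(geo, quiet_model(), "2c", "b", seed=11)
        u = bud.data["z_um"].to_numpy() / geo.dome_radius
        assert sps.kstest(u, "uniform").statistic < 0.02

    def test_reporters_uncorrelated_without_shared_factor(self):
        # with sigma_ext = 0 the two reporters' residuals are independent
        geo = MeristemGeometry(30.0, 100_000)
        model = quiet_model(baseline=50.0, sigma_int=0.5)
        bud, _ = generate_bud(geo, model, "2c", "b", seed=13)
        r = np.corrcoef(np.log(bud.signal("c1")), np.log(bud.signal("c2")))[0, 1]
        assert abs(r) < 0.02


class TestClosedFormNoise:
    def test_no_noise_degenerate(self):
        assert closed_form_noise(0.0, 0.0) == (0.0, 0.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            closed_form_noise(-0.1, 0.2)

    @pytest.mark.parametrize("sigma_ext,sigma_int", [(0.5, 0.0), (0.5, 0.5)])
    def test_matches_monte_carlo(self, sigma_ext, sigma_int):
        # independent oracle: 1e6 simulated cells through the raw estimator
        rng = np.random.default_rng(42)
        n = 1_000_000
        ext = np.exp(rng.normal(0, sigma_ext, n))
        c1 = 100.0 * ext * np.exp(rng.normal(0, sigma_int, n))
        c2 = 100.0 * ext * np.exp(rng.normal(0, sigma_int, n))
        est = pooled_noise(c1, c2)
        eta2_ext, eta2_int = closed_form_noise(sigma_ext, sigma_int)
        assert est.eta2_ext == pytest.approx(eta2_ext, rel=0.01)
        if eta2_int > 0:
            assert est.eta2_int == pytest.approx(eta2_int, rel=0.01)
        else:
            assert est.eta2_int == pytest.approx(0.0, abs=1e-12)

    def test_known_values(self):
        eta2_ext, eta2_int = closed_form_noise(0.5, 0.5)
        assert eta2_ext == pytest.approx(math.exp(0.25) - 1.0)
        assert eta2_int == pytest.approx(math.exp(0.25) * (math.exp(0.25) - 1.0))


class TestGenerateCohort:
    def test_counts_and_stage_labels(self):
        sims = generate_cohort({"1a": 2, "2c": 3}, None, None, seed=1)
        assert len(sims) == 5
        assert [b.stage for b, _ in sims] == ["1a", "1a", "2c", "2c", "2c"]

    def test_substream_independence(self):
        # changing one stage's count leaves other buds' realizations alone
        a = generate_cohort({"1a": 2, "2c": 3}, None, None, seed=9)
        b = generate_cohort({"1a": 5, "2c": 3}, None, None, seed=9)
        a_2c = [t for t, _ in a if t.stage == "2c"]
        b_2c = [t for t, _ in b if t.stage == "2c"]
        for x, y in zip(a_2c, b_2c):
            assert x.equals(y, rtol=0.0)

    def test_master_seed_changes_all_buds(self):
        a = generate_cohort({"2c": 3}, None, None, seed=1)
        b = generate_cohort({"2c": 3}, None, None, seed=2)
        for (x, _), (y, _) in zip(a, b):
            assert not x.equals(y)

    def test_derived_seeds_distinct(self):
        seeds = {derive_bud_seed(0, s, k) for s in ("1a", "2c") for k in range(50)}
        assert len(seeds) == 100


class TestApplyPerturbation:
    def test_oryzalin_cell_loss(self):
        geo = MeristemGeometry(30.0, 100)
        geo2, model2 = apply_perturbation("oryzalin", geo, ExpressionModel())
        assert geo2.n_cells == 41
        assert model2 == ExpressionModel()

    def test_hydroxyurea_cell_loss(self):
        geo = MeristemGeometry(30.0, 100)
        geo2, _ = apply_perturbation("hydroxyurea", geo, ExpressionModel())
        assert geo2.n_cells == 67

    def test_mock_identity(self):
        geo, model = MeristemGeometry(30.0, 100), ExpressionModel(patch_rate=2.0)
        assert apply_perturbation("mock", geo, model) == (geo, model)

    def test_uniform_induction_flattens_pattern(self):
        model = ExpressionModel(foci=four_sepal_foci(), patch_rate=3.0, baseline=20.0)
        _, model2 = apply_perturbation("2,4-D", MeristemGeometry(30.0, 100), model)
        assert model2.foci == () and model2.patch_rate == 0.0
        assert model2.baseline == 120.0
        assert model2.sigma_ext == model.sigma_ext
        assert model2.sigma_int == model.sigma_int

    def test_bead_control_is_measurement_only(self):
        geo, model = apply_perturbation(
            "beads", MeristemGeometry(30.0, 100), ExpressionModel()
        )
        assert geo.placement_rule == "cluster"
        assert model.sigma_ext == model.sigma_int == 0.0
        assert model.sigma_meas > 0.0
        bud, _ = generate_bud(geo, model, "2c", "beads", seed=1)
        # all "nuclei" co-located at the apex
        assert bud.data[["x_um", "y_um"]].abs().to_numpy().max() == 0.0
        est = pooled_noise(bud.signal("c1"), bud.signal("c2"))
        # residual apparent noise is small: measurement error only
        assert est.eta2_int < 0.05

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ScenarioError):
            apply_perturbation("caffeine", MeristemGeometry(30.0, 10), ExpressionModel())
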