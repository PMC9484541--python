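import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import epsurv as ep
from epsurv.models import (
    DurationPowerLaw,
    FermiCurve,
    FitFailureError,
    InsufficientDesignError,
    ModifiedPelegFermiModel,
    PelegFermiCoefficients,
    PelegFermiModel,
    StageOneFit,
)

EFS_GRID = np.array([250.0, 500.0, 750.0, 1000.0, 1250.0, 1500.0, 2000.0, 2500.0, 3000.0])
N_GRID = np.arange(10, 100, 10)


def surface_xy(coeffs, efs=EFS_GRID, ns=N_GRID):
    e, n = np.meshgrid(efs, ns, indexing="ij")
    X = np.column_stack([e.ravel(), n.ravel()])
    y = np.asarray(ep.survival_probability(X[:, 0], coeffs.ec(X[:, 1]), coeffs.ac(X[:, 1])))
    return X, y


class TestSurvivalProbability:
    def test_half_kill_at_threshold(self):
        assert ep.survival_probability(800.0, 800.0, 200.0) == 0.5

    def test_high_field_limit(self):
        assert ep.survival_probability(1e9, 500.0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_one_slope_below_threshold(self):
        # E = Ec - Ac is the point one slope-constant below the midpoint
        assert ep.survival_probability(400.0, 500.0, 100.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), rel=1e-12
        )

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            ep.survival_probability(100.0, 100.0, 0.0)

    @given(
        efs=st.floats(0, 5000),
        ec=st.floats(1, 5000),
        ac=st.floats(200, 2000),
    )
    @settings(deadline=None)
    def test_output_in_unit_interval_and_decreasing(self, efs, ec, ac):
        s = ep.survival_probability(efs, ec, ac)
        assert 0.0 < s < 1.0
        assert ep.survival_probability(efs + 10.0, ec, ac) < s


class TestDecayLaws:
    def test_ec_at_zero_pulses_is_e0(self, kyse150_100):
        assert ep.ec_of_n(kyse150_100, 0) == kyse150_100.e0

    @pytest.mark.parametrize(
        "cell_line, duration, expected",
        [("KYSE-150", 100, 459.227), ("MGC-823", 100, 85.012)],
    )
    def test_published_thresholds(self, cell_line, duration, expected):
        c = ep.builtin_coefficients(cell_line, duration)[0]
        assert ep.ec_of_n(c, 100) == pytest.approx(expected, abs=0.5)

    @pytest.mark.parametrize(
        "cell_line, duration, expected",
        [("QBC-939", 100, 174.474), ("L-02", 100, 401.307), ("MIA PaCa-2", 25, 1328.199)],
    )
    def test_threshold_alias(self, cell_line, duration, expected):
        c = ep.builtin_coefficients(cell_line, duration)[0]
        assert ep.ec_threshold(c, 100) == pytest.approx(expected, abs=0.5)


class TestStageOne:
    def test_exact_recovery(self):
        y = ep.survival_probability(EFS_GRID, 800.0, 200.0)
        curve = FermiCurve().fit(EFS_GRID, y)
        assert curve.ec_ == pytest.approx(800.0, rel=1e-6)
        assert curve.ac_ == pytest.approx(200.0, rel=1e-6)
        assert curve.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(42)
        y = ep.survival_probability(EFS_GRID, 800.0, 200.0) + rng.normal(0, 0.02, EFS_GRID.size)
        curve = FermiCurve().fit(EFS_GRID, y)
        assert curve.ec_ == pytest.approx(800.0, rel=0.05)
        assert curve.ac_ == pytest.approx(200.0, rel=0.05)

    def test_constant_viability_fails(self):
        with pytest.raises(FitFailureError):
            FermiCurve().fit(EFS_GRID, np.ones_like(EFS_GRID))

    def test_too_few_levels(self):
        with pytest.raises(InsufficientDesignError):
            FermiCurve().fit([100.0, 200.0], [0.9, 0.1])

    def test_dataset_wrapper(self, noiseless_dataset, kyse150_100):
        fit = ep.fit_stage1(noiseless_dataset, "KYSE-150", 100, 50)
        assert fit.ec_n == pytest.approx(kyse150_100.ec(50), rel=1e-5)
        assert fit.ac_n == pytest.approx(kyse150_100.ac(50), rel=1e-5)


class TestStageTwo:
    @staticmethod
    def stage1_from(e0, k1, a0=600.0, k2=0.005, ns=N_GRID):
        return [
            StageOneFit(int(n), e0 * np.exp(-k1 * n), a0 * np.exp(-k2 * n), 1.0, 9)
            for n in ns
        ]

    def test_exact_exponential(self):
        coeffs = ep.fit_stage2(self.stage1_from(2000.0, 0.012))
        assert coeffs.e0 == pytest.approx(2000.0, rel=1e-6)
        assert coeffs.k1 == pytest.approx(0.012, rel=1e-6)
        assert coeffs.r2_e == pytest.approx(1.0, abs=1e-9)

    def test_negative_decay_rate_recovered(self):
        # Ac growing with N (negative k2) occurs in the published database
        coeffs = ep.fit_stage2(self.stage1_from(2000.0, 0.012, a0=600.0, k2=-0.004))
        assert coeffs.a0 == pytest.approx(600.0, rel=1e-6)
        assert coeffs.k2 == pytest.approx(-0.004, rel=1e-6)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(7)
        fits = [
            StageOneFit(int(n), 2000 * np.exp(-0.012 * n) * (1 + rng.normal(0, 0.05)),
                        600 * np.exp(-0.005 * n), 1.0, 9)
            for n in N_GRID
        ]
        coeffs = ep.fit_stage2(fits)
        assert coeffs.e0 == pytest.approx(2000.0, rel=0.10)
        assert coeffs.k1 == pytest.approx(0.012, rel=0.10)

    def test_too_few_pulse_numbers(self):
        with pytest.raises(InsufficientDesignError):
            ep.fit_stage2(self.stage1_from(2000.0, 0.012, ns=[10, 20]))


class TestTwoStepFit:
    def test_roundtrip_kyse410(self):
        truth = ep.builtin_coefficients("KYSE-410", 100)[0]
        cfg = ep.GeneratorConfig(truths=[truth], noise_sd=0.0)
        ds = ep.generate_dataset(cfg)
        fit = ep.fit_peleg_fermi(ds, "KYSE-410", 100)
        for name in ("e0", "k1", "a0", "k2"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), rel=1e-3)
        assert fit.organ == "esophagus"

    def test_missing_pulse_number_warns_and_fits(self, noiseless_dataset, kyse150_100):
        frame = noiseless_dataset.frame
        ds = ep.ViabilityDataset(frame[frame["pulse_number"] != 50])
        fit = ep.fit_peleg_fermi(ds, "KYSE-150", 100)
        assert fit.e0 == pytest.approx(kyse150_100.e0, rel=1e-3)

    def test_all_dead_data_fails(self):
        frame = pd.DataFrame(
            {
                "cell_line": "SW-480",
                "organ": "colon",
                "pulse_duration_us": 100.0,
                "pulse_number": np.repeat(N_GRID, EFS_GRID.size),
                "efs_v_cm": np.tile(EFS_GRID, N_GRID.size),
                "replicate": 1,
                "viability_pct": 0.0,
            }
        )
        with pytest.raises((FitFailureError, InsufficientDesignError)):
            with pytest.warns(UserWarning):
                ep.fit_peleg_fermi(ep.ViabilityDataset(frame), "SW-480", 100)

    def test_sklearn_protocol(self, kyse150_100):
        X, y = surface_xy(kyse150_100)
        model = PelegFermiModel().fit(X, y)
        assert model.score(X, y) == pytest.approx(1.0, abs=1e-9)
        cloned = clone(model)  # params survive cloning, fitted state does not
        assert cloned.get_params() == model.get_params()
        np.testing.assert_allclose(model.predict(X), y, atol=1e-7)


class TestModifiedModel:
    def test_exact_double_exponential_predictions(self):
        n = np.arange(10, 100, 10, dtype=float)
        ec = 1500 * np.exp(-0.02 * n) + 800 * np.exp(-0.002 * n)
        ac = 400 * np.exp(-0.01 * n) + 200 * np.exp(-0.001 * n)
        fits = [StageOneFit(int(v), e, a, 1.0, 9) for v, e, a in zip(n, ec, ac)]
        model = ModifiedPelegFermiModel().fit_from_stage1(fits)
        # terms may permute; assert on the predicted decay curves
        pred_ec = model.e1_ * np.exp(-model.k1_ * n) + model.e2_ * np.exp(-model.k2_ * n)
        np.testing.assert_allclose(pred_ec, ec, rtol=1e-6)
        assert model.r2_e_ == pytest.approx(1.0, abs=1e-9)

    def test_nests_single_exponential(self):
        n = np.arange(10, 100, 10, dtype=float)
        ec = 2000 * np.exp(-0.012 * n)
        ac = 600 * np.exp(-0.005 * n)
        fits = [StageOneFit(int(v), e, a, 1.0, 9) for v, e, a in zip(n, ec, ac)]
        model = ModifiedPelegFermiModel().fit_from_stage1(fits)
        pred_ec = model.e1_ * np.exp(-model.k1_ * n) + model.e2_ * np.exp(-model.k2_ * n)
        np.testing.assert_allclose(pred_ec, ec, rtol=1e-4)

    def test_requires_five_pulse_numbers(self):
        fits = [StageOneFit(n, 1000.0, 300.0, 1.0, 9) for n in (10, 20, 30)]
        with pytest.raises(InsufficientDesignError):
            ep.fit_modified_peleg_fermi(fits)


class TestPowerLaw:
    def test_exact_power_law(self):
        tp = np.array([0.025, 0.05, 0.075, 0.1])
        e = 500.0 * tp ** (-0.4)
        coeffs = ep.fit_power_law(tp, e)
        assert coeffs.a == pytest.approx(500.0, rel=1e-9)
        assert coeffs.b == pytest.approx(-0.4, rel=1e-9)

    def test_two_point_closed_form(self):
        coeffs = ep.fit_power_law([0.025, 0.1], [1000.0, 500.0])
        assert coeffs.b == pytest.approx(-0.5, rel=1e-12)
        assert coeffs.a == pytest.approx(1000.0 * 0.025**0.5, rel=1e-12)

    def test_single_duration_rejected(self):
        with pytest.raises(InsufficientDesignError):
            ep.fit_power_law([0.1, 0.1], [500.0, 500.0])


class TestSurfacesAndTables:
    def test_threshold_identity_on_surface(self, kyse150_100):
        ns = np.array([10, 50, 100])
        ecs = kyse150_100.ec(ns)
        surf = ep.survival_surface(kyse150_100, ecs, ns)
        np.testing.assert_array_equal(np.diag(surf), 0.5)

    def test_rows_decreasing_in_efs_and_in_n(self, kyse150_100):
        # over the assay's design range; at very low fields the shrinking
        # slope constant can raise S slightly with N, which is exactly why
        # an explicit lethal threshold is imposed downstream
        efs = np.linspace(250, 3000, 30)
        ns = np.arange(10, 100, 10)
        surf = ep.survival_surface(kyse150_100, efs, ns)
        assert (np.diff(surf, axis=1) < 0).all()  # decreasing in EFS
        assert (np.diff(surf, axis=0) <= 0).all()  # more pulses never help (k1,k2>0)

    def test_single_point_grid(self, kyse150_100):
        assert ep.survival_surface(kyse150_100, [500.0], [10]).shape == (1, 1)

    def test_coefficient_table_layout(self, kyse150_100):
        table = ep.coefficient_table([kyse150_100])
        assert list(table.columns) == [
            "organ", "cell_line", "pulse_duration_us",
            "e0", "k1", "r2_e", "a0", "k2", "r2_a", "ec100",
        ]
        assert table.loc[0, "ec100"] == pytest.approx(459.227, abs=0.5)

    def test_esophagus_block_range(self, complete_db):
        eso = [
            ep.coefficients_from_row(r)
            for _, r in complete_db.query(
                "organ == 'esophagus' and pulse_duration_us == 100"
            ).iterrows()
        ]
        table = ep.coefficient_table(eso)
        assert int(table["ec100"].min()) == 459
        assert int(table["ec100"].max()) == 684

    def test_empty_table(self):
        assert len(ep.coefficient_table([])) == 0
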