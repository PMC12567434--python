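"""Type A/B evaluators, volumetric items, calibration and repeatability."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mubudget import (
    InsufficientDataError,
    SchemaError,
    dilution_relative_u,
    fit_calibration,
    pooled_repeatability,
    prediction_u,
    read_calibration_csv,
    read_repeatability_csv,
    read_sst_csv,
    rectangular_u,
    sst_statistics,
    temperature_volume_effect,
    triangular_u,
    type_a_uncertainty,
    volume_item,
)
from mubudget.evaluators import CalibrationRegression


class TestTypeA:
    @pytest.mark.parametrize(
        "sd, m, expect",
        [(0.003807, 6, 0.0015542), (0.001568, 6, 0.00064013)],
    )
    def test_sd_of_mean_from_replicate_injections(self, sd, m, expect):
        u, dof = type_a_uncertainty(sd=sd, m=m)
        assert u == pytest.approx(expect, abs=5e-8)
        assert dof == m - 1

    def test_constant_observations_give_zero(self):
        u, dof = type_a_uncertainty([5.0] * 6)
        assert u == 0.0 and dof == 5

    def test_single_measurement_refused(self):
        with pytest.raises(InsufficientDataError):
            type_a_uncertainty(sd=0.1, m=1)


class TestDistributionConversions:
    @pytest.mark.parametrize(
        "hw, expect", [(0.0001, 0.000058), (0.02, 0.0115), (0.0, 0.0)]
    )
    def test_rectangular(self, hw, expect):
        assert rectangular_u(hw) == pytest.approx(expect, abs=5e-7 if hw < 1e-3 else 5e-5)

    @pytest.mark.parametrize(
        "hw, expect", [(0.1, 0.04082), (0.04, 0.01633), (0.015, 0.00612)]
    )
    def test_triangular(self, hw, expect):
        assert triangular_u(hw) == pytest.approx(expect, abs=5e-6)

    def test_negative_half_width_rejected(self):
        with pytest.raises(ValueError):
            rectangular_u(-0.1)
        with pytest.raises(ValueError):
            triangular_u(-0.1)

    @given(hw=st.floats(1e-9, 1e3))
    def test_rectangular_exceeds_triangular(self, hw):
        assert rectangular_u(hw) > triangular_u(hw)


class TestVolumes:
    @pytest.mark.parametrize(
        "v, hw, u",
        [(100, 0.084, 0.04850), (25, 0.021, 0.01212), (5, 0.0042, 0.00242),
         (2, 0.00168, 0.00097)],
    )
    def test_temperature_effect(self, v, hw, u):
        got_hw, got_u = temperature_volume_effect(v, 4.0, 2.1e-4)
        assert got_hw == pytest.approx(hw, rel=1e-9)
        assert got_u == pytest.approx(u, abs=5e-6)

    def test_zero_excursion(self):
        assert temperature_volume_effect(100, 0.0) == (0.0, 0.0)

    @pytest.mark.parametrize(
        "nominal, tol, u_combined, relative",
        [
            (2, 0.01, 0.0042, 0.0021),
            (5, 0.015, 0.00659, 0.0013),
            (25, 0.04, 0.02034, 0.0008),
            (100, 0.1, 0.06339, 0.0006),
        ],
    )
    def test_glassware_budget_rows(self, nominal, tol, u_combined, relative):
        item = volume_item(nominal, tol)
        assert item.u_combined == pytest.approx(u_combined, rel=2e-3)
        assert item.relative == pytest.approx(relative, abs=5e-5)

    def test_combined_reduces_to_u_cal_without_temperature(self):
        item = volume_item(2, 0.01, delta_t=0.0)
        assert item.u_combined == item.u_cal

    def test_dilution_chain_relative(self):
        rels = [0.0021, 0.001318, 0.0008136, 0.0006339]
        assert dilution_relative_u(rels) == pytest.approx(0.002683, rel=2e-3)

    def test_dilution_single_and_symmetry(self):
        assert dilution_relative_u([0.003]) == pytest.approx(0.003)
        assert dilution_relative_u([0.002, 0.002]) == pytest.approx(
            0.002 * math.sqrt(2)
        )

    def test_dilution_empty_rejected(self):
        with pytest.raises(ValueError):
            dilution_relative_u([])


class TestCalibration:
    def test_perfect_line_recovered(self):
        c = np.array([0.1, 0.2, 0.3, 0.4])
        reg = fit_calibration(c, 2.0 * c)
        assert reg.slope == pytest.approx(2.0, rel=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.sres == pytest.approx(0.0, abs=1e-12)

    def test_five_level_design_ssdx(self, rng):
        c = np.repeat([0.12, 0.16, 0.20, 0.24, 0.28], 3)
        reg = fit_calibration(c, 350 * c + rng.normal(0, 0.3, c.size))
        assert reg.ssdx == pytest.approx(0.048, rel=1e-12)
        assert reg.n == 15 and reg.c_bar == pytest.approx(0.2)
        assert reg.levels == (0.12, 0.16, 0.20, 0.24, 0.28)
        assert reg.replicates == (3, 3, 3, 3, 3)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="ingular"):
            fit_calibration([0.2, 0.2, 0.2], [1.0, 1.1, 0.9])

    def test_sres_estimates_noise_sd(self, rng):
        # simulation oracle: mean Sres over many fits approaches sigma
        c = np.repeat([0.12, 0.16, 0.20, 0.24, 0.28], 3)
        sigma = 0.3
        sres = [
            fit_calibration(c, 350 * c + rng.normal(0, sigma, c.size)).sres
            for _ in range(400)
        ]
        assert np.mean(sres) == pytest.approx(sigma, rel=0.05)


class TestPredictionU:
    REG = CalibrationRegression(
        slope=1.0, intercept=0.0, sres=8.136e-4, n=15, c_bar=0.2, ssdx=0.048,
        levels=(0.12, 0.16, 0.2, 0.24, 0.28), replicates=(3,) * 5,
    )

    def test_published_worked_example(self):
        # Sres/a1 = 8.136e-4 back-computed from the printed u(Cx) = 0.000393
        assert prediction_u(self.REG, p=6, cx=0.2005) == pytest.approx(
            0.000393, abs=5e-7
        )

    def test_zero_residual_sd_gives_zero(self):
        reg = CalibrationRegression(1.0, 0.0, 0.0, 15, 0.2, 0.048, (0.2,), (15,))
        assert prediction_u(reg, 6, 0.25) == 0.0

    def test_minimum_at_mean_concentration(self):
        at_mean = prediction_u(self.REG, 6, 0.2)
        for cx in (0.12, 0.18, 0.22, 0.28):
            assert prediction_u(self.REG, 6, cx) > at_mean

    @given(p=st.integers(1, 50))
    def test_decreasing_in_replicates(self, p):
        assert prediction_u(self.REG, p + 1, 0.2) < prediction_u(self.REG, p, 0.2)

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            prediction_u(self.REG, 0, 0.2)


class TestRepeatability:
    def test_constant_study_gives_zero(self):
        study = pooled_repeatability(np.full((3, 6), 7.0))
        assert study.sr == 0.0 and study.sr_mean == 0.0
        assert study.n_total == 18 and study.dof == 15

    def test_pooled_sd_recovers_within_run_sigma(self, rng):
        sigma = 0.05
        srs = [
            pooled_repeatability(rng.normal(99.7, sigma, (3, 6))).sr
            for _ in range(400)
        ]
        assert np.mean(srs) == pytest.approx(sigma, rel=0.05)

    def test_sr_mean_uses_total_count(self, rng):
        study = pooled_repeatability(rng.normal(99.7, 0.05, (3, 6)))
        assert study.sr_mean == pytest.approx(study.sr / math.sqrt(18))

    def test_per_run_divisor_option(self, rng):
        m = rng.normal(99.7, 0.05, (3, 6))
        total = pooled_repeatability(m)
        per_run = pooled_repeatability(m, divisor="per_run")
        assert per_run.sr_mean == pytest.approx(total.sr / math.sqrt(6))

    @pytest.mark.parametrize("shape", [(1, 6), (3, 1), (6,)])
    def test_degenerate_shapes_rejected(self, shape, rng):
        with pytest.raises(InsufficientDataError):
            pooled_repeatability(rng.normal(0, 1, shape))


class TestSst:
    def test_published_sd_of_means(self, rng):
        # series constructed to reproduce the printed sds exactly
        rt = 3.808 + 0.003807 * _unit_sd_series(6)
        area = 70.509 + 0.001568 * _unit_sd_series(6)
        s = sst_statistics(rt, area)
        assert s.retention.sd_of_mean == pytest.approx(0.0015542, abs=5e-8)
        assert s.area.sd_of_mean == pytest.approx(0.00064013, abs=5e-9)
        assert s.passed

    def test_constant_series_passes_with_zero_cv(self):
        s = sst_statistics([3.8] * 6, [70.5] * 6)
        assert s.retention.cv_pct == pytest.approx(0.0, abs=1e-12)
        assert s.area.cv_pct == pytest.approx(0.0, abs=1e-12)
        assert s.passed

    def test_noisy_area_fails_criterion(self, rng):
        area = 70.5 + 3.0 * _unit_sd_series(6)  # CV ~4% > 2%
        s = sst_statistics([3.8] * 5 + [3.81], area)
        assert not s.area.passed and not s.passed


def _unit_sd_series(n):
    """Deterministic n-vector with sample sd exactly 1 and mean 0."""
    x = np.arange(n, dtype=float)
    x -= x.mean()
    return x / x.std(ddof=1)


class TestCsvReaders:
    def test_calibration_round_trip(self, tmp_path):
        p = tmp_path / "cal.csv"
        p.write_text("concentration,response\n0.12,42.0\n0.2,70.5\n0.28,98.7\n")
        df = read_calibration_csv(p)
        reg = fit_calibration(df[["concentration", "response"]].to_numpy())
        assert reg.n == 3

    def test_repeatability_pivot(self, tmp_path):
        p = tmp_path / "rep.csv"
        rows = ["run,replicate,value"]
        for run in (1, 2):
            for rep in (1, 2, 3):
                rows.append(f"{run},{rep},{99.7 + 0.01 * rep}")
        p.write_text("\n".join(rows) + "\n")
        m = read_repeatability_csv(p)
        assert m.shape == (2, 3)

    def test_missing_column_reported(self, tmp_path):
        p = tmp_path / "sst.csv"
        p.write_text("injection,retention_time\n1,3.8\n")
        with pytest.raises(SchemaError, match="area"):
            read_sst_csv(p)
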