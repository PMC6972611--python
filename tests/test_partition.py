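"""Integral-to-amount conversion and binodal/spinodal changepoint estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from llps_nmr import (ScenarioConfig, fit_binodal, fit_spinodal,
                      generate_partition_series, partition_from_integrals,
                      reduce_partition_table)

BINODAL, SPINODAL, SLOPE = 0.43, 0.71, 0.5


def piecewise(x, binodal=BINODAL, spinodal=SPINODAL, slope=SLOPE):
    return np.minimum(binodal + slope * np.asarray(x, float), spinodal)


class TestPartitionFromIntegrals:
    @pytest.mark.parametrize("I_a, I_a_star, expected", [
        (2.0, 1.0, (1.0, 2.0)),
        (5.0, 0.0, (0.0, 3.0)),       # single phase: no starred signal
        (0.9, 0.1, (0.3, 2.7)),
    ])
    def test_proportional_split(self, I_a, I_a_star, expected):
        n_star, mother = partition_from_integrals(I_a, I_a_star, 3.0)
        assert n_star == pytest.approx(expected[0])
        assert mother == pytest.approx(expected[1])

    def test_no_signal_error(self):
        with pytest.raises(ValueError, match="no signal"):
            partition_from_integrals(0.0, 0.0, 3.0)

    @given(I_a=st.floats(1e-6, 1e6), I_a_star=st.floats(0.0, 1e6),
           scale=st.floats(1e-3, 1e3))
    @settings(deadline=None)
    def test_conservation_and_scale_invariance(self, I_a, I_a_star, scale):
        """Outputs sum to c_tot exactly; only the integral ratio matters."""
        n_star, mother = partition_from_integrals(I_a, I_a_star, 3.0)
        assert n_star + mother == pytest.approx(3.0, abs=1e-13)
        assert 0.0 <= n_star <= 3.0
        n2, _ = partition_from_integrals(I_a * scale, I_a_star * scale, 3.0)
        assert n2 == pytest.approx(n_star, rel=1e-9, abs=1e-12)


class TestFitBinodal:
    def test_noiseless_intercept(self):
        x = np.array([0.05, 0.10, 0.15, 0.20])
        intercept, slope, _, _ = fit_binodal(x, 0.43 + 0.5 * x, breakpoint=0.56)
        assert intercept == pytest.approx(0.43, abs=1e-12)
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_flat_data_gives_intercept_at_level(self):
        x = np.array([0.05, 0.10, 0.15, 0.20])
        intercept, slope, _, _ = fit_binodal(x, np.full(4, 0.6), breakpoint=0.56)
        assert intercept == pytest.approx(0.6)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_binodal([0.1, 0.2], [0.5, 0.55], breakpoint=0.56)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_binodal([0.1, 0.1, 0.1], [0.5, 0.5, 0.5], breakpoint=0.56)

    def test_noisy_recovery_unbiased(self, rng):
        """Monte Carlo: 200-point fits recover the true intercept within 2 SE."""
        intercepts, ses = [], []
        for _ in range(100):
            x = rng.uniform(0.02, 0.5, 200)
            y = 0.43 + 0.5 * x + rng.normal(0, 0.01, 200)
            b, _, se_b, _ = fit_binodal(x, y, breakpoint=0.56)
            intercepts.append(b)
            ses.append(se_b)
        mean_se = np.mean(ses) / np.sqrt(100)
        assert np.mean(intercepts) == pytest.approx(0.43, abs=2 * np.mean(ses))
        assert abs(np.mean(intercepts) - 0.43) < 4 * mean_se


class TestFitSpinodal:
    def test_noiseless_piecewise_exact(self):
        x = np.linspace(0.05, 1.1, 12)
        est = fit_spinodal(x, piecewise(x))
        assert est.plateau_detected
        assert est.binodal == pytest.approx(BINODAL, abs=1e-6)
        assert est.spinodal == pytest.approx(SPINODAL, abs=1e-6)
        assert est.breakpoint == pytest.approx((SPINODAL - BINODAL) / SLOPE, abs=1e-4)
        assert est.binodal < est.spinodal

    def test_pure_linear_flags_undetermined(self):
        x = np.linspace(0.05, 1.1, 12)
        with pytest.warns(UserWarning, match="undetermined"):
            est = fit_spinodal(x, 0.43 + 0.5 * x)
        assert not est.plateau_detected
        assert est.spinodal is None

    def test_manual_breakpoint(self):
        x = np.linspace(0.05, 1.1, 12)
        est = fit_spinodal(x, piecewise(x), breakpoint=0.56)
        assert est.binodal == pytest.approx(BINODAL, abs=1e-12)
        assert est.spinodal == pytest.approx(SPINODAL, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_spinodal([0.1, 0.3, 0.5, 0.7, 0.9], piecewise([0.1, 0.3, 0.5, 0.7, 0.9]))

    def test_noisy_series_median_error(self, scenario):
        """Generator-default noise: median boundary error < 0.02 mM over 50 seeds."""
        err_b, err_s = [], []
        for seed in range(1, 51):
            df = generate_partition_series(scenario, n_points=12, seed=seed)
            red = reduce_partition_table(df[["pH", "I_a", "I_a_star"]],
                                         scenario.c_tot_mM, scenario.pKa)
            est = fit_spinodal(red["n_star_mM"], red["c_IbuH_L1_mM"])
            assert est.plateau_detected
            err_b.append(abs(est.binodal - BINODAL))
            err_s.append(abs(est.spinodal - SPINODAL))
        assert np.median(err_b) < 0.02
        assert np.median(err_s) < 0.02

    def test_scale_invariance_of_boundaries(self, scenario):
        """Uniform integral rescaling leaves the boundary estimates unchanged."""
        df = generate_partition_series(scenario, n_points=12, seed=7)
        red1 = reduce_partition_table(df[["pH", "I_a", "I_a_star"]], 3.0, 4.4)
        df2 = df.copy()
        df2[["I_a", "I_a_star"]] *= 137.0
        red2 = reduce_partition_table(df2[["pH", "I_a", "I_a_star"]], 3.0, 4.4)
        e1 = fit_spinodal(red1["n_star_mM"], red1["c_IbuH_L1_mM"])
        e2 = fit_spinodal(red2["n_star_mM"], red2["c_IbuH_L1_mM"])
        assert e1.binodal == pytest.approx(e2.binodal, rel=1e-9)
        assert e1.spinodal == pytest.approx(e2.spinodal, rel=1e-9)


def test_reduce_raw_table_roundtrip(scenario):
    """Zero-noise raw tables reduce back to the exact ground-truth columns."""
    quiet = ScenarioConfig(seed=1, sigma_integral=0.0, sigma_pH=0.0)
    df = generate_partition_series(quiet, n_points=12, seed=1)
    red = reduce_partition_table(df[["pH", "I_a", "I_a_star"]],
                                 quiet.c_tot_mM, quiet.pKa)
    np.testing.assert_allclose(red["n_star_mM"], df["true_n_star_mM"], rtol=1e-10)
    np.testing.assert_allclose(red["c_IbuH_L1_mM"], df["true_c_IbuH_L1_mM"], rtol=1e-10)
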