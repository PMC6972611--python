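"""Generator contracts: determinism, conservation, and zero-noise roundtrips."""

import numpy as np
import pandas as pd
import pytest

from llps_nmr import (ScenarioConfig, fit_spinodal, fit_stejskal_tanner,
                      generate_partition_series, generate_peak_table,
                      generate_pfgste_decay, generate_titration_series,
                      noe_distance_table, generate_noesy_intensities,
                      generate_relaxation_pair, reduce_partition_table,
                      tauc_from_t1t2, titration_onset)


class TestTitrationSeries:
    def test_zero_dosing_constant_ph(self):
        from llps_nmr import SpeciationConfig
        quiet = ScenarioConfig(seed=0,
                               titration=SpeciationConfig(rate_mL_per_min=0.0))
        df = generate_titration_series(quiet, t_end_min=10, n_steps=11)
        assert df["pH"].nunique() == 1

    def test_ph_monotone_decreasing(self, scenario):
        df = generate_titration_series(scenario, t_end_min=40, n_steps=81)
        assert np.all(np.diff(df["pH_true"]) < 0)

    def test_turbidity_onset_at_binodal(self, scenario):
        t_on, c_on = titration_onset(scenario)
        assert c_on == pytest.approx(scenario.binodal_mM, abs=1e-3)
        df = generate_titration_series(scenario, t_end_min=40, n_steps=161)
        # the turbid flag flips exactly where c_IbuH crosses the binodal
        flipped = df["turbid"] != (df["time_s"] / 60.0 > t_on)
        assert flipped.sum() <= 1  # at most the grid point straddling the onset

    def test_infeasible_dosing_rejected(self, scenario):
        with pytest.raises(ValueError):
            generate_titration_series(scenario, t_end_min=-5)


class TestPartitionSeries:
    def test_determinism(self, scenario):
        a = generate_partition_series(scenario, 12, seed=1)
        b = generate_partition_series(scenario, 12, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_exact_boundary_recovery(self):
        quiet = ScenarioConfig(seed=0, sigma_integral=0.0, sigma_pH=0.0)
        df = generate_partition_series(quiet, 12, seed=0)
        red = reduce_partition_table(df[["pH", "I_a", "I_a_star"]],
                                     quiet.c_tot_mM, quiet.pKa)
        est = fit_spinodal(red["n_star_mM"], red["c_IbuH_L1_mM"])
        assert est.binodal == pytest.approx(quiet.binodal_mM, abs=1e-6)
        assert est.spinodal == pytest.approx(quiet.spinodal_mM, abs=1e-6)

    def test_boundary_estimates_unbiased(self, scenario):
        """Monte Carlo over 100 seeds: no systematic boundary bias."""
        binodals, spinodals = [], []
        for seed in range(100):
            df = generate_partition_series(scenario, 12, seed=seed)
            red = reduce_partition_table(df[["pH", "I_a", "I_a_star"]],
                                         scenario.c_tot_mM, scenario.pKa)
            est = fit_spinodal(red["n_star_mM"], red["c_IbuH_L1_mM"])
            binodals.append(est.binodal)
            spinodals.append(est.spinodal)
        # Monte-Carlo error of the mean ~ sd/10; allow 4x
        assert np.mean(binodals) == pytest.approx(
            scenario.binodal_mM, abs=4 * np.std(binodals) / 10)
        assert np.mean(spinodals) == pytest.approx(
            scenario.spinodal_mM, abs=4 * np.std(spinodals) / 10)

    def test_true_columns_conserve_mass(self, scenario):
        df = generate_partition_series(scenario, 12, seed=5)
        assert np.all(df["true_n_star_mM"] + (scenario.c_tot_mM - df["true_n_star_mM"])
                      == scenario.c_tot_mM)
        assert np.all(df["true_n_star_mM"].between(0, scenario.c_tot_mM))


class TestDecayGenerator:
    def test_zero_noise_exact_exponential(self):
        curve = generate_pfgste_decay(100e-12, sigma=0.0, I0=42.0)
        np.testing.assert_allclose(curve.intensity, 42.0 * np.exp(-curve.b * 100e-12))

    def test_seeded_reproducibility(self):
        a = generate_pfgste_decay(100e-12, sigma=0.01, seed=9)
        b = generate_pfgste_decay(100e-12, sigma=0.01, seed=9)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_fit_recovery_bias_under_noise(self):
        Ds = [fit_stejskal_tanner(generate_pfgste_decay(
                  16.3e-12, sigma=0.01, seed=s)).D for s in range(200)]
        assert np.mean(Ds) == pytest.approx(16.3e-12, rel=0.005)


class TestRelaxationGenerator:
    def test_zero_noise_roundtrip(self, scenario):
        m = generate_relaxation_pair(0.9e-9, 400e6, sigma=0.0)
        res = tauc_from_t1t2(m)
        assert res.tau_c == pytest.approx(0.9e-9, rel=1e-9)

    def test_below_detection_in_extreme_narrowing(self):
        m = generate_relaxation_pair(1e-13, 400e6, sigma=0.0)
        res = tauc_from_t1t2(m)
        assert not res.converged

    def test_recovery_over_seeds(self):
        taus = [tauc_from_t1t2(generate_relaxation_pair(
                    0.9e-9, 400e6, sigma=0.02, seed=s)).tau_c
                for s in range(1, 101)]
        assert np.median(taus) == pytest.approx(0.9e-9, rel=0.05)


class TestNoesyGenerator:
    def test_determinism(self):
        a = generate_noesy_intensities(seed=3)
        b = generate_noesy_intensities(seed=3)
        assert a.intensities == b.intensities

    def test_recovery_within_tolerance_over_seeds(self):
        errs = {"a*-b*": [], "b*-c*": []}
        truth = {"a*-b*": 2.04, "b*-c*": 2.71}
        for seed in range(1, 101):
            table = noe_distance_table(
                generate_noesy_intensities(truth, sigma=0.02, seed=seed)
            ).set_index("pair")
            for pair, d in truth.items():
                errs[pair].append(table.loc[pair, "distance_angstrom"] - d)
        for pair in truth:
            # d ~ I^(1/6): 2% intensity noise -> ~0.5% distance scatter
            assert abs(np.mean(errs[pair])) < 0.01


class TestPeakTable:
    def test_single_phase_no_starred_peaks(self, scenario):
        table = generate_peak_table(scenario, n_star_mM=0.0)
        assert not table["peak"].str.endswith("*").any()

    def test_twin_offsets(self, scenario):
        table = generate_peak_table(scenario, n_star_mM=0.3)
        merged = table[table["phase"] == "dense"].merge(
            table[table["phase"] == "mother"],
            left_on=table[table["phase"] == "dense"]["peak"].str.rstrip("*"),
            right_on="peak", suffixes=("_dense", "_mother"))
        offsets = merged["ppm_mother"] - merged["ppm_dense"]
        expected = merged["kind_mother"].map({"aliphatic": 0.3, "aromatic": 0.5})
        np.testing.assert_allclose(offsets, expected)

    def test_integral_split_matches_partition_model(self, scenario):
        n_star = 0.9
        table = generate_peak_table(scenario, n_star_mM=n_star)
        one = table[table["peak"].isin(["a", "a*"])].set_index("peak")
        frac = one.loc["a*", "integral"] / one["integral"].sum()
        assert frac == pytest.approx(n_star / scenario.c_tot_mM, rel=1e-12)
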