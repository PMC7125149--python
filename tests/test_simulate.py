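import numpy as np
import pandas as pd
import pytest

from polystate import (ConfigurationError, SimulationConfig, ValidationError,
                       close_profiles, simulate_fraction_profiles,
                       simulate_gene_sets, simulate_polysome_experiment,
                       welch_t_test)
from polystate import test_fraction_difference as run_fraction_difference
from polystate.simulate import planted_means, steady_config

PLANTED = {
    "steady": 0.7, "transcription_up": 0.05, "transcription_down": 0.05,
    "repressed": 0.1, "derepressed": 0.1,
}


class TestSimulationConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_isoforms": 0},
        {"n_isoforms": 10, "n_replicates": 1},
        {"n_isoforms": 10, "state_proportions": {"steady": 0.5}},
        {"n_isoforms": 10, "state_proportions": {"mystery": 1.0}},
        {"n_isoforms": 10, "dispersion": -0.1},
        {"n_isoforms": 10, "effect_fold": 0.0},
        {"n_isoforms": 10, "noise_model": "cauchy"},
        {"n_isoforms": 10, "detection_fraction": 1.5},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestPolysomeExperiment:
    def test_same_seed_gives_identical_output(self):
        cfg = SimulationConfig(n_isoforms=100, seed=11,
                               state_proportions=PLANTED)
        m1, t1 = simulate_polysome_experiment(cfg)
        m2, t2 = simulate_polysome_experiment(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        m1, _ = simulate_polysome_experiment(SimulationConfig(n_isoforms=50, seed=1))
        m2, _ = simulate_polysome_experiment(SimulationConfig(n_isoforms=50, seed=2))
        assert not np.array_equal(m1.values.to_numpy(), m2.values.to_numpy())

    def test_steady_only_truth_and_stage_ratio(self):
        cfg = SimulationConfig(n_isoforms=4000, seed=5)
        matrix, truth = simulate_polysome_experiment(cfg)
        assert set(truth["state"]) == {"steady"}
        a = matrix.fraction_values("polysome", "E13").to_numpy().mean()
        b = matrix.fraction_values("polysome", "E16").to_numpy().mean()
        assert b / a == pytest.approx(1.0, abs=0.02)

    def test_truth_covers_every_isoform_exactly_once(self):
        cfg = SimulationConfig(n_isoforms=211, seed=2, state_proportions=PLANTED)
        matrix, truth = simulate_polysome_experiment(cfg)
        assert sorted(truth["isoform_id"]) == sorted(matrix.isoform_ids)
        assert not truth["isoform_id"].duplicated().any()

    def test_design_is_two_stages_three_fractions(self):
        cfg = SimulationConfig(n_isoforms=5, n_replicates=4, seed=0)
        matrix, _ = simulate_polysome_experiment(cfg)
        assert matrix.values.shape == (5, 2 * 3 * 4)
        meta = matrix.sample_meta
        assert set(meta["stage"]) == {"E13", "E16"}
        counts = meta.groupby(["stage", "fraction"]).size()
        assert (counts == 4).all()

    @pytest.mark.parametrize("state,fraction,stage,expected", [
        ("derepressed", "polysome", "E16", 200.0),
        ("derepressed", "polysome", "E13", 50.0),
        ("derepressed", "input", "E16", 50.0),
        ("repressed", "polysome", "E16", 12.5),
        ("repressed", "input", "E16", 50.0),
        ("transcription_up", "input", "E16", 200.0),
        ("transcription_up", "monosome", "E16", 200.0),
        ("monosome_shift", "monosome", "E16", 200.0),
        ("monosome_shift", "polysome", "E16", 50.0),
        ("steady", "polysome", "E16", 50.0),
    ])
    def test_planted_state_modulates_the_right_cell(self, state, fraction,
                                                    stage, expected):
        cfg = SimulationConfig(
            n_isoforms=60, seed=0, effect_fold=4.0, baseline_mean=50.0,
            state_proportions={s: 1 / 6 for s in
                               ("steady", "transcription_up", "transcription_down",
                                "repressed", "derepressed", "monosome_shift")})
        means, truth = planted_means(cfg)
        rows = truth["state"] == state
        assert (means.loc[rows.to_numpy(), (stage, fraction)] == expected).all()

    def test_mean_fidelity_within_three_standard_errors(self):
        cfg = SimulationConfig(n_isoforms=3000, seed=13, state_proportions=PLANTED)
        matrix, truth = simulate_polysome_experiment(cfg)
        dere = truth.loc[truth["state"] == "derepressed", "isoform_id"]
        obs = matrix.values.loc[dere, matrix.samples_for("E16", "polysome")].to_numpy()
        mu = 200.0
        se = np.sqrt(mu + 0.1 * mu**2) / np.sqrt(obs.size)
        assert abs(obs.mean() - mu) < 3 * se

    def test_below_detection_planting_lowers_input_means(self):
        cfg = SimulationConfig(n_isoforms=1000, seed=4, state_proportions=PLANTED,
                               detection_fraction=0.5)
        means, truth = planted_means(cfg)
        below = truth["below_detection"].to_numpy()
        assert (truth.loc[below, "state"] == "derepressed").all()
        for stage in ("E13", "E16"):
            assert (means.loc[below, (stage, "input")]
                    < cfg.detection_threshold).all()
            # polysome planting is untouched by the detection flag
            assert (means.loc[below, (stage, "polysome")] >= 50.0).all()

    def test_mass_conserving_mode_moves_mass_into_monosome(self):
        cfg = SimulationConfig(n_isoforms=10, seed=0, mass_conserving=True,
                               state_proportions={"repressed": 1.0})
        means, _ = planted_means(cfg)
        # polysome loses 50 - 12.5 = 37.5; monosome gains it
        assert (means[("E16", "monosome")] == 87.5).all()
        assert (means[("E16", "polysome")] == 12.5).all()

    def test_lognormal_noise_model_matches_target_mean(self):
        cfg = SimulationConfig(n_isoforms=4000, seed=9, noise_model="lognormal")
        matrix, _ = simulate_polysome_experiment(cfg)
        obs = matrix.values.to_numpy()
        assert obs.mean() == pytest.approx(50.0, rel=0.02)
        assert (obs > 0).all()

    def test_steady_config_strips_planted_effects(self):
        cfg = SimulationConfig(n_isoforms=10, seed=0, state_proportions=PLANTED,
                               detection_fraction=0.3)
        null = steady_config(cfg)
        assert null.state_proportions == {"steady": 1.0}
        assert null.detection_fraction == 0


class TestFractionProfiles:
    def test_zero_shift_zero_noise_gives_identical_conditions(self):
        prof = simulate_fraction_profiles(shift_delta=0.0, noise_sd=0.0, seed=1)
        a = prof[prof["condition"] == "baseline"][["F", "M", "LP", "HP"]].to_numpy()
        b = prof[prof["condition"] == "shifted"][["F", "M", "LP", "HP"]].to_numpy()
        assert np.array_equal(a, b)
        res = run_fraction_difference(prof, "HP", "F")
        assert res.p == 1.0 and res.degenerate

    def test_noiseless_shift_arithmetic(self):
        prof = simulate_fraction_profiles(baseline_composition=(0.4, 0.3, 0.2, 0.1),
                                          shift_delta=0.2, noise_sd=0.0, seed=1)
        closed = close_profiles(prof)
        shifted = closed[closed["condition"] == "shifted"]
        base = closed[closed["condition"] == "baseline"]
        assert (shifted["HP"] - shifted["F"]).to_numpy() == pytest.approx(0.1)
        assert (base["HP"] - base["F"]).to_numpy() == pytest.approx(-0.3)

    def test_negative_composition_rejected(self):
        with pytest.raises(ValidationError):
            simulate_fraction_profiles(baseline_composition=(-0.1, 0.5, 0.3, 0.3))

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValidationError, match="exceeds the free-pool"):
            simulate_fraction_profiles(baseline_composition=(0.1, 0.3, 0.3, 0.3),
                                       shift_delta=0.2)

    def test_raw_profiles_are_non_negative(self):
        prof = simulate_fraction_profiles(noise_sd=0.5, seed=3)
        assert (prof[["F", "M", "LP", "HP"]].to_numpy() > 0).all()

    def test_welch_power_for_planted_shift(self):
        """Monte-Carlo power: the HP - F Welch test at alpha = 0.05 detects a
        0.2 mass shift (noise_sd 0.05, n = 3) in well over 80% of seeds."""
        rejections = 0
        n_runs = 300
        for seed in range(n_runs):
            prof = simulate_fraction_profiles(n_replicates=3, shift_delta=0.2,
                                              noise_sd=0.05, seed=seed)
            res = run_fraction_difference(prof, "HP", "F")
            rejections += res.p < 0.05
        assert rejections / n_runs >= 0.8


class TestGeneSets:
    @pytest.mark.parametrize("n_uni,n_in,n_tg,overlap", [
        (20, 5, 8, 0),
        (20, 5, 8, 5),
        (100, 10, 40, 7),
        (30, 6, 6, 6),
    ])
    def test_planted_overlap_is_exact(self, n_uni, n_in, n_tg, overlap):
        universe, inp, tgt = simulate_gene_sets(n_uni, n_in, n_tg, overlap, seed=2)
        assert len(universe) == n_uni
        assert len(inp) == n_in and len(tgt) == n_tg
        assert len(inp & tgt) == overlap
        assert inp <= set(universe) and tgt <= set(universe)

    def test_full_overlap_means_subset(self):
        _, inp, tgt = simulate_gene_sets(50, 5, 20, 5, seed=0)
        assert inp <= tgt

    @pytest.mark.parametrize("args", [
        (20, 5, 8, 6),     # overlap > min size
        (10, 12, 3, 1),    # input larger than universe
        (10, 6, 6, 1),     # union exceeds universe
    ])
    def test_infeasible_configurations_rejected(self, args):
        with pytest.raises(ConfigurationError):
            simulate_gene_sets(*args, seed=0)
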