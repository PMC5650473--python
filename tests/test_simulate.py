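"""The synthetic sorted-fraction generator: ages, gates, readouts, sites."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from primmus.ergodic import age_density, cumulative_to_time
from primmus.simulate import (CycleGeometry, INTERPHASE_FRACTIONS,
                              MITOTIC_FRACTIONS, SimulationConfig,
                              TrajectoryModel, assign_gates,
                              default_impurity_matrix, sample_population,
                              simulate_interphase_dataset,
                              simulate_phosphosites, simulate_silac_matrix,
                              simulate_tmt_reporters)

LN2 = np.log(2.0)


@pytest.fixture(scope="module")
def population():
    cfg = SimulationConfig(seed=1, n_cells=100_000)
    return cfg, sample_population(cfg)


class TestSamplePopulation:
    def test_age_support_and_cdf_endpoint(self, population):
        _, ages = population
        assert ages.min() >= 0.0 and ages.max() <= 1.0
        assert np.mean(ages <= 1.0) == 1.0

    def test_g1_mass_matches_printed_frequency(self, population):
        # 21% of cells lie before the G1 boundary position t=0.16
        _, ages = population
        tG1 = float(cumulative_to_time(0.21))
        assert np.mean(ages <= tG1) == pytest.approx(0.21, abs=0.01)

    def test_mean_content_is_2ln2(self, population):
        _, ages = population
        assert np.mean(np.exp2(ages)) == pytest.approx(2 * LN2, rel=0.005)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=42, n_cells=1000)
        assert np.array_equal(sample_population(cfg), sample_population(cfg))

    def test_rejects_nonpositive_n(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError):
            sample_population(cfg, n=0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_cells": -5},
        {"gate_purity": 0.4},
        {"dropout_rate": 1.0},
        {"compression": 0.0},
        {"phase_boundaries": (0.5, 0.4, 0.9, 1.0)},
    ])
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestAssignGates:
    def test_pure_gates_are_deterministic(self, population):
        cfg, ages = population
        geo = CycleGeometry.from_config(cfg)
        rng = np.random.default_rng(0)
        gates = assign_gates(ages, geo.interphase_edges, INTERPHASE_FRACTIONS,
                             1.0, rng)
        assert gates[np.argmin(np.abs(ages - 0.05))] == "G1"
        true_phase = np.searchsorted(geo.interphase_edges, ages, side="right") - 1
        for i, lab in enumerate(INTERPHASE_FRACTIONS):
            sel = gates == lab
            # confusion matrix diagonal at purity 1
            assert np.all(true_phase[sel] == i)

    def test_m_gate_mitotic_index_matches_purity(self, population):
        cfg, ages = population
        geo = CycleGeometry.from_config(cfg)
        rng = np.random.default_rng(1)
        gates = assign_gates(ages, geo.interphase_edges, INTERPHASE_FRACTIONS,
                             0.96, rng)
        m_window = geo.interphase_edges[-2]
        mitotic = ages >= m_window
        m_gate = gates == "M"
        assert np.mean(mitotic[m_gate]) == pytest.approx(0.96, abs=0.02)

    def test_rejects_overlapping_boundaries(self, population):
        _, ages = population
        with pytest.raises(ValueError):
            assign_gates(ages, (0.0, 0.5, 0.4, 1.0), ("a", "b", "c"), 1.0,
                         np.random.default_rng(0))


class TestTrajectories:
    @pytest.mark.parametrize("cls", [
        "bulk_exponential", "histone_plateau", "mitotic_peak",
        "prometaphase_degraded", "anaphase_degraded", "constant_per_cell"])
    def test_positive_everywhere(self, cls):
        tr = TrajectoryModel("x", cls)
        t = np.linspace(0, 1, 501)
        assert np.all(tr.abundance(t) > 0)

    def test_bulk_doubles_over_cycle(self):
        tr = TrajectoryModel("x", "bulk_exponential", baseline=3.0)
        assert tr.abundance(1.0) == pytest.approx(2 * tr.abundance(0.0))

    @pytest.mark.parametrize("cls", ["prometaphase_degraded", "anaphase_degraded"])
    def test_degraded_non_increasing_in_window(self, cls):
        tr = TrajectoryModel("x", cls, shape={"drop_window": (0.90, 0.95),
                                              "residual": 0.3})
        t = np.linspace(0.90, 0.95, 101)
        assert np.all(np.diff(tr.abundance(t)) <= 1e-12)
        assert tr.abundance(0.99) == pytest.approx(0.3 * tr.abundance(0.89))


class TestSilacReadout:
    def test_bulk_g1_ratio_matches_quadrature_oracle(self, population):
        cfg, ages = population
        nf = dataclasses.replace(cfg, noise_cv=0.0, dropout_rate=0.0)
        geo = CycleGeometry.from_config(cfg)
        rng = np.random.default_rng(2)
        gates = assign_gates(ages, geo.interphase_edges, INTERPHASE_FRACTIONS,
                             1.0, rng)
        panel = [TrajectoryModel("B", "bulk_exponential"),
                 TrajectoryModel("C", "constant_per_cell")]
        m, truth = simulate_silac_matrix(ages, gates, panel, nf, rng=rng)
        # independent oracle: gate mean of 2**t over [0, tG1] divided by the
        # asynchronous mean, both by quadrature
        tG1 = geo.interphase_edges[1]
        num, _ = quad(lambda t: np.exp2(t) * age_density(t), 0, tG1)
        den, _ = quad(age_density, 0, tG1)
        oracle = (num / den) / (2 * LN2)
        assert m.loc["B", "G1"] == pytest.approx(oracle, rel=0.01)

    def test_constant_protein_is_unity_everywhere(self, population):
        cfg, ages = population
        nf = dataclasses.replace(cfg, noise_cv=0.0, dropout_rate=0.0)
        geo = CycleGeometry.from_config(cfg)
        rng = np.random.default_rng(3)
        gates = assign_gates(ages, geo.interphase_edges, INTERPHASE_FRACTIONS,
                             1.0, rng)
        m, _ = simulate_silac_matrix(
            ages, gates, [TrajectoryModel("C", "constant_per_cell")], nf, rng=rng)
        assert np.allclose(m.loc["C"], 1.0)

    def test_anaphase_degraded_residual_ratio(self, population):
        # degradation completing at the Ana boundary puts the Ana gate at
        # exactly the residual fraction of prophase levels
        cfg, _ = population
        nf = dataclasses.replace(cfg, noise_cv=0.0, dropout_rate=0.0,
                                 n_cells=50_000)
        geo = CycleGeometry.from_config(cfg)
        from primmus.simulate import sample_mitotic_population
        rng = np.random.default_rng(4)
        ages = sample_mitotic_population(nf, geo, rng=rng)
        gates = assign_gates(ages, geo.mitotic_edges, MITOTIC_FRACTIONS, 1.0, rng)
        t_ana = geo.subphase_window("Ana")[0]
        tr = TrajectoryModel("A", "anaphase_degraded",
                             shape={"residual": 0.3,
                                    "drop_window": (t_ana - 1e-9, t_ana)})
        m, _ = simulate_silac_matrix(ages, gates, [tr], nf, rng=rng,
                                     fractions=MITOTIC_FRACTIONS,
                                     standard_ages=ages)
        assert m.loc["A", "Ana"] / m.loc["A", "Pro"] == pytest.approx(0.30, abs=1e-9)

    def test_empty_gate_raises(self, population):
        cfg, ages = population
        gates = np.full(ages.shape, "G1", dtype=object)
        with pytest.raises(ValueError):
            simulate_silac_matrix(ages, gates, [TrajectoryModel("B", "bulk_exponential")],
                                  cfg, fractions=["G1", "S"])


class TestTmtForwardModel:
    def test_identity_matrix_is_proportional(self):
        cfg = SimulationConfig(seed=0, noise_cv=0.0)
        true = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        obs = simulate_tmt_reporters(true, np.eye(3), 1.0, cfg)
        ratio = obs.to_numpy() / true.to_numpy()
        assert np.allclose(ratio, ratio[0, 0])

    def test_two_channel_mixing(self):
        cfg = SimulationConfig(seed=0, noise_cv=0.0)
        true = pd.DataFrame([[100.0, 0.0]], columns=["a", "b"])
        M = np.array([[0.9, 0.1], [0.1, 0.9]])
        obs = simulate_tmt_reporters(true, M, 1.0, cfg, intensity_scale=1.0)
        assert np.allclose(obs.to_numpy(), [[90.0, 10.0]])

    def test_compression_halves_log_ratio(self):
        cfg = SimulationConfig(seed=0, noise_cv=0.0)
        true = pd.DataFrame([[4.0, 1.0]], columns=["a", "b"])
        obs = simulate_tmt_reporters(true, np.eye(2), 0.5, cfg)
        assert obs.iloc[0, 0] / obs.iloc[0, 1] == pytest.approx(2.0)

    def test_rejects_negative_input(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError):
            simulate_tmt_reporters(pd.DataFrame([[-1.0, 1.0]]), np.eye(2), 1.0, cfg)

    def test_default_impurity_matrix_column_stochastic(self):
        M = default_impurity_matrix(6)
        assert np.all(M >= 0) and np.all(M.sum(axis=0) <= 1.0 + 1e-12)


class TestPhosphosites:
    def test_windows_are_15mers_centred_on_residue(self, phospho_data):
        meta, _, _ = phospho_data
        assert (meta["sequence_window"].str.len() == 15).all()
        assert (meta["sequence_window"].str[7] == meta["amino_acid"]).all()

    def test_planted_classes_noise_free(self):
        cfg = SimulationConfig(seed=2, noise_cv=0.0, dropout_rate=0.0)
        _, quant, truth = simulate_phosphosites(
            cfg, n_sites={"early_riser": 5, "late_riser": 5, "flat": 5})
        med = quant.T.groupby(level="fraction", sort=False).median().T
        early = med[truth["class_label"] == "early_riser"]
        assert (early["G1"] <= early["S"]).all()
        assert (early["S"] <= early["G2"]).all()
        assert (early["G2"] < early["M"]).all()
        assert (early["G2"] > early["G1"]).all()
        flat = med[truth["class_label"] == "flat"]
        assert np.allclose(flat.max(axis=1) / flat.min(axis=1), 1.0)

    def test_residue_frequencies_configurable(self):
        cfg = SimulationConfig(seed=3)
        meta, _, _ = simulate_phosphosites(
            cfg, n_sites={"flat": 6000}, residue_freqs=(0.832, 0.158, 0.010))
        freq = (meta["amino_acid"] == "S").mean()
        assert freq == pytest.approx(0.832, abs=0.02)


class TestDatasetDeterminism:
    def test_identical_config_identical_output(self):
        cfg = SimulationConfig(seed=9, n_cells=5000,
                               n_proteins={"bulk_exponential": 50,
                                           "histone_plateau": 5,
                                           "mitotic_peak": 5,
                                           "constant_per_cell": 5})
        a = simulate_interphase_dataset(cfg)
        b = simulate_interphase_dataset(cfg)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)
        pd.testing.assert_frame_equal(a.truth, b.truth)
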