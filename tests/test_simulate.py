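"""Generator correctness: Markov dynamics, spectral shaping, cohort determinism."""

import numpy as np
import pytest
from scipy import stats as sct

from srsleep.features import BandScheme, epoch_features
from srsleep.simulate import (
    LIGHT,
    DARK,
    ConfigurationError,
    LinePreset,
    SimConfig,
    VigilanceState,
    default_presets,
    simulate_cohort,
    simulate_hypnogram,
    synthesize_signals,
)


def single_phase_preset(P, base):
    """Preset whose LIGHT and DARK matrices are both P."""
    return LinePreset(
        line_id="X",
        phase_transition_matrices={LIGHT: np.array(P), DARK: np.array(P)},
        band_profile=dict(base.band_profile),
        emg_level=dict(base.emg_level),
        eeg_amplitude=dict(base.eeg_amplitude),
    )


def stationary_oracle(P):
    """Independent stationary distribution: solve pi P = pi, sum(pi) = 1."""
    P = np.asarray(P, float)
    A = np.vstack([P.T - np.eye(3), np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


class TestSimulateHypnogram:
    def test_unreachable_state_never_appears(self, presets, sim_config):
        P = [[0.9, 0.1, 0.0], [0.1, 0.9, 0.0], [0.3, 0.3, 0.4]]
        preset = single_phase_preset(P, presets["IR"])
        h = simulate_hypnogram(preset, sim_config, 7, initial_state=VigilanceState.NREMS)
        assert not (h.states == VigilanceState.REMS).any()

    def test_absorbing_identity_matrix(self, presets, sim_config):
        preset = single_phase_preset(np.eye(3), presets["IR"])
        h = simulate_hypnogram(preset, sim_config, 7, initial_state=VigilanceState.WAKE)
        assert h.n_epochs == 20700
        assert (h.states == VigilanceState.WAKE).all()

    def test_stationary_distribution_recovery(self, presets):
        """Empirical state fractions of a long ergodic chain match the
        analytic stationary distribution within 1% absolute."""
        P = presets["IR"].phase_transition_matrices[LIGHT]
        preset = single_phase_preset(P, presets["IR"])
        # 999 000 epochs = 1110 h, single phase (lights never go off)
        cfg = SimConfig(n_days=1, recording_hours=1110.0, lights_off_zt=1110.0, seed=1)
        h = simulate_hypnogram(preset, cfg, 42)
        frac = np.bincount(h.states, minlength=3) / h.n_epochs
        assert np.abs(frac - stationary_oracle(P)).max() < 0.01

    def test_sampled_rows_match_matrix(self, presets):
        """Next-state frequencies from each state agree with the matrix row
        (chi-square goodness of fit not rejected at alpha = 0.01)."""
        P = presets["HR"].phase_transition_matrices[LIGHT]
        preset = single_phase_preset(P, presets["HR"])
        cfg = SimConfig(n_days=1, recording_hours=1110.0, lights_off_zt=1110.0, seed=1)
        s = simulate_hypnogram(preset, cfg, 99).states
        for i in range(3):
            idx = np.flatnonzero(s[:-1] == i)
            obs = np.bincount(s[idx + 1], minlength=3).astype(float)
            exp = P[i] * obs.sum()
            keep = exp > 0
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            p = sct.chi2.sf(chi2, keep.sum() - 1)
            assert p > 0.01

    def test_deterministic_under_seed(self, presets, sim_config):
        a = simulate_hypnogram(presets["LR"], sim_config, 5)
        b = simulate_hypnogram(presets["LR"], sim_config, 5)
        assert np.array_equal(a.states, b.states)

    def test_phase_switch_at_lights_off(self, presets, sim_config):
        """DARK-phase dynamics differ from LIGHT: an absorbing DARK matrix
        freezes the state from ZT12 on."""
        preset = single_phase_preset(np.eye(3), presets["IR"])
        preset.phase_transition_matrices[LIGHT] = presets["IR"].phase_transition_matrices[LIGHT]
        h = simulate_hypnogram(preset, sim_config, 3)
        dark = h.states[10800:]
        assert (dark == dark[0]).all()
        assert len(np.unique(h.states[:10800])) == 3

    def test_non_stochastic_matrix_rejected(self, presets):
        P = [[0.5, 0.4, 0.0], [0.1, 0.9, 0.0], [0.3, 0.3, 0.4]]
        with pytest.raises(ConfigurationError, match="sum to 1"):
            single_phase_preset(P, presets["IR"])

    def test_zero_length_recording_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(recording_hours=0.0)


class TestPresets:
    def test_rows_stochastic_and_nonnegative(self, presets):
        for p in presets.values():
            for phase in (LIGHT, DARK):
                P = p.phase_transition_matrices[phase]
                assert (P >= 0).all()
                assert np.abs(P.sum(axis=1) - 1).max() <= 1e-12

    def test_nrems_to_rems_ordering(self, presets):
        """HR enters REMS from NREMS more readily than IR, and IR than LR,
        in both light phases."""
        i, j = VigilanceState.NREMS, VigilanceState.REMS
        for phase in (LIGHT, DARK):
            hr = presets["HR"].phase_transition_matrices[phase][i, j]
            ir = presets["IR"].phase_transition_matrices[phase][i, j]
            lr = presets["LR"].phase_transition_matrices[phase][i, j]
            assert hr > ir >= lr

    def test_lr_theta_alpha_depressed_in_nrems(self, presets):
        for band_idx in (1, 2):  # theta, alpha
            lr = presets["LR"].band_profile[VigilanceState.NREMS][band_idx]
            assert lr < presets["HR"].band_profile[VigilanceState.NREMS][band_idx]
            assert lr < presets["IR"].band_profile[VigilanceState.NREMS][band_idx]

    def test_atonia_ordering_enforced(self, presets):
        bad_emg = {VigilanceState.WAKE: 1.0, VigilanceState.NREMS: 2.0, VigilanceState.REMS: 0.5}
        p = presets["IR"]
        with pytest.raises(ConfigurationError, match="atonia"):
            LinePreset("bad", {k: v.copy() for k, v in p.phase_transition_matrices.items()},
                       dict(p.band_profile), bad_emg, dict(p.eeg_amplitude))


class TestSynthesizeSignals:
    def test_measured_band_fractions_match_targets(self, presets, short_config):
        """Direct DFT on each synthesized epoch recovers the target band
        profile with mean absolute error < 0.05."""
        preset = presets["HR"]
        h = simulate_hypnogram(preset, short_config, 11)
        rec = synthesize_signals(h, preset, short_config, 12)
        feats = epoch_features(rec, BandScheme())
        scheme = BandScheme()
        err = []
        for k, name in enumerate(scheme.band_names):
            target = np.array([preset.band_profile[VigilanceState(s)][k] for s in h.states])
            err.append(np.abs(feats[f"rel_{name}"].to_numpy() - target))
        assert np.mean(err) < 0.05

    def test_epoch_rms_matches_state_amplitude(self, presets, short_config):
        preset = presets["IR"]
        h = simulate_hypnogram(preset, short_config, 21)
        rec = synthesize_signals(h, preset, short_config, 22)
        eeg = rec.eeg.reshape(h.n_epochs, -1)
        rms = np.sqrt((eeg**2).mean(axis=1))
        target = np.array([preset.eeg_amplitude[VigilanceState(s)] for s in h.states])
        # spectral shaping makes epoch power exact up to float rounding
        assert np.allclose(rms, target, rtol=1e-9)

    def test_zero_emg_level_gives_silent_rems(self, presets, short_config):
        p = presets["IR"]
        preset = LinePreset(
            "z", {k: v.copy() for k, v in p.phase_transition_matrices.items()},
            dict(p.band_profile),
            {VigilanceState.WAKE: 30.0, VigilanceState.NREMS: 10.0, VigilanceState.REMS: 0.0},
            dict(p.eeg_amplitude),
        )
        h = simulate_hypnogram(preset, short_config, 31)
        rec = synthesize_signals(h, preset, short_config, 32)
        emg = rec.emg.reshape(h.n_epochs, -1)
        rems = h.states == VigilanceState.REMS
        if rems.any():
            assert np.abs(emg[rems]).max() == 0.0

    def test_length_mismatch_rejected(self, presets, short_config, sim_config):
        h = simulate_hypnogram(presets["IR"], short_config, 1)
        with pytest.raises(ValueError, match="epochs"):
            synthesize_signals(h, presets["IR"], sim_config, 2)


class TestCohort:
    def test_cohort_size_and_reproducibility(self, presets):
        cfg = SimConfig(n_days=1, recording_hours=2.0, seed=77)
        c1 = simulate_cohort(presets, cfg)
        c2 = simulate_cohort(presets, cfg)
        assert len(c1.animals) == 24
        assert len({a.animal_id for a in c1.animals}) == 24
        for a, b in zip(c1.animals, c2.animals):
            assert a.animal_id == b.animal_id and a.line == b.line
            for ha, hb in zip(a.hypnograms, b.hypnograms):
                assert np.array_equal(ha.states, hb.states)

    def test_days_chain_markov_state(self, presets):
        cfg = SimConfig(n_days=2, recording_hours=2.0, seed=5)
        c = simulate_cohort(presets, cfg)
        a = c.animals[0]
        assert len(a.hypnograms) == 2
        assert a.hypnograms[0].day_index == 0 and a.hypnograms[1].day_index == 1
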