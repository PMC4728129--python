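"""Extraction of the 33 variables: window arithmetic, round trips, assembly."""

import numpy as np
import pytest

from ephyscensus import (CellModelParams, ExtractionConfig, Protocol,
                         extract_all, measure_iv_currents, monosynapticity,
                         simulate_iv_protocol,
                         simulate_synaptic_protocol, synaptic_charge_curve)
from ephyscensus.features import VARIABLE_NAMES, detect_minis, step_train_features
from ephyscensus.model import Recording
from ephyscensus.simulate import step_best_current, synaptic_charge
from ephyscensus.spikes import SpikeTrain


class TestIVWindows:
    def test_zero_trace_measures_zero(self):
        rec = Recording(Protocol.IV_STEPS, np.zeros((10, 1500)),
                        [{"command_mv": v} for v in range(-65, 116, 20)])
        table = measure_iv_currents(rec)
        assert (table[["i_na", "i_k_peak", "i_ks", "i_kt"]].to_numpy() == 0).all()

    def test_kt_is_peak_minus_steady_exactly(self, quiet_cell):
        table = measure_iv_currents(quiet_cell[Protocol.IV_STEPS])
        np.testing.assert_allclose(table["i_kt"], table["i_k_peak"] - table["i_ks"])

    def test_sustained_current_has_no_transient_component(self):
        p = CellModelParams(na_max=0.0, kt_max=0.0, ks_max=200.0, noise_sd=0.0)
        table = measure_iv_currents(simulate_iv_protocol(p))
        # KS rises within ~5 time constants, so early peak == steady value
        assert np.abs(table["i_kt"]).max() < 0.02 * 200.0

    def test_short_sweep_rejected(self):
        rec = Recording(Protocol.IV_STEPS, np.zeros((1, 800)), [{"command_mv": 0}])
        with pytest.raises(ValueError):
            measure_iv_currents(rec)

    def test_windowed_amplitudes_match_generator(self, quiet_params, quiet_cell):
        from ephyscensus.simulate import ks_amplitude, na_amplitude
        table = measure_iv_currents(quiet_cell[Protocol.IV_STEPS])
        v = table["v"].to_numpy()
        np.testing.assert_allclose(table["i_na"],
                                   np.minimum(na_amplitude(v, quiet_params), 0.0),
                                   atol=1.0)
        np.testing.assert_allclose(table["i_ks"], ks_amplitude(v, quiet_params),
                                   atol=1.0)


class TestIVRoundTrip:
    def test_activation_potentials_within_half_mv(self, quiet_params, quiet_features):
        assert quiet_features["I_Na activation"] == pytest.approx(
            quiet_params.na_act, abs=0.5)
        assert quiet_features["I_KS activation"] == pytest.approx(
            quiet_params.ks_act, abs=0.5)
        assert quiet_features["I_KT activation"] == pytest.approx(
            quiet_params.kt_act, abs=0.5)

    def test_max_currents_within_two_percent(self, quiet_params, quiet_features):
        assert quiet_features["I_Na"] == pytest.approx(quiet_params.na_max, rel=0.02)
        assert quiet_features["I_KS"] == pytest.approx(quiet_params.ks_max, rel=0.02)
        assert quiet_features["I_KT"] == pytest.approx(quiet_params.kt_max, rel=0.02)


class TestStepFeatures:
    def test_shape_variables_match_generator(self, quiet_params, quiet_features):
        f = quiet_features
        assert f["Spike threshold"] == pytest.approx(quiet_params.spike_thresh, abs=0.5)
        assert f["Spike amplitude"] == pytest.approx(quiet_params.spike_amp, abs=1.0)
        assert f["Spike rise-time"] == pytest.approx(quiet_params.spike_rise, abs=0.05)
        assert f["Spike width"] == pytest.approx(quiet_params.spike_width, abs=0.1)

    def test_tail_is_membrane_time_constant(self, quiet_params, quiet_features):
        assert quiet_features["Tail"] == pytest.approx(quiet_params.tau_m, rel=0.05)

    def test_best_current_within_one_step(self, quiet_params, quiet_features):
        assert abs(quiet_features["I best"]
                   - step_best_current(quiet_params)) <= 20.0
        assert quiet_features["N spikes step"] == pytest.approx(
            quiet_params.spike_gain, rel=0.1)

    def test_isi_and_accommodation_definitions(self, quiet_params, quiet_features):
        assert quiet_features["Spike ISI"] == pytest.approx(
            quiet_params.isi_first, abs=0.3)
        assert quiet_features["Spike ISI accommodation"] == pytest.approx(
            quiet_params.isi_accom, abs=0.05)
        assert quiet_features["Spike accommodation"] == pytest.approx(
            quiet_params.amp_accom, abs=0.03)

    def test_isi_metrics_from_explicit_train(self):
        # ISIs [10, 20] -> first ISI 10, accommodation ratio 2
        rec = Recording(Protocol.CURRENT_STEPS, np.full((1, 6000), -65.0),
                        [{"current_pa": 100, "onset_ms": 100, "duration_ms": 300}])
        train = SpikeTrain(spike_times=np.array([150.0, 160.0, 180.0]),
                           kink_potentials=np.array([-40.0] * 3),
                           peak_potentials=np.array([10.0] * 3),
                           amplitudes=np.array([50.0, 40.0, 35.0]),
                           rise_times=np.array([0.4] * 3),
                           half_widths=np.array([1.0] * 3))
        out = step_train_features(rec, [train])
        assert out["Spike ISI"] == 10.0
        assert out["Spike ISI accommodation"] == 2.0
        assert out["Spike accommodation"] == pytest.approx(40.0 / 50.0)

    def test_single_spike_gives_shape_but_no_train_metrics(self):
        rec = Recording(Protocol.CURRENT_STEPS, np.full((1, 6000), -65.0),
                        [{"current_pa": 20, "onset_ms": 100, "duration_ms": 300}])
        train = SpikeTrain(spike_times=np.array([150.0]),
                           kink_potentials=np.array([-40.0]),
                           peak_potentials=np.array([15.0]),
                           amplitudes=np.array([55.0]),
                           rise_times=np.array([0.5]),
                           half_widths=np.array([1.2]))
        out = step_train_features(rec, [train])
        assert out["Spike threshold"] == -40.0
        for key in ("Spike ISI", "Spike ISI accommodation", "Spike accommodation"):
            assert key not in out


class TestCosineRoundTrip:
    def test_resonance_within_fifteen_percent(self, quiet_params, quiet_features):
        assert quiet_features["Spiking resonance"] == pytest.approx(
            quiet_params.cos_resonance, rel=0.15)

    def test_wave_buildup_recovered(self, quiet_params, quiet_features):
        assert quiet_features["Wave buildup"] == pytest.approx(
            quiet_params.wave_buildup, abs=0.7)

    def test_mean_spikes_per_wave_tracks_tuning(self, quiet_params, quiet_features):
        from ephyscensus.fits import diffexp
        from ephyscensus.simulate import cosine_tuning
        a, b, c, d = cosine_tuning(quiet_params)
        periods = np.array([10.0, 20.0, 100 / 3, 40.0, 50.0])
        expected = float(np.mean(diffexp(periods, a, b, c, d)))
        assert quiet_features["N spikes cosine"] == pytest.approx(expected, abs=0.12)

    def test_identical_sweeps_drive_jitter_to_clamp(self, quiet_features):
        assert quiet_features["Jitter"] <= np.log(1e-12) + 1e-6


class TestSynaptic:
    def test_zero_current_zero_charge(self):
        p = CellModelParams(syn_amp=0.0, syn_facil=0.0, poly_amp=0.0, noise_sd=0.0)
        q = synaptic_charge_curve(simulate_synaptic_protocol(p))
        np.testing.assert_allclose(q.to_numpy(), 0.0, atol=1e-9)

    def test_rectangular_response_area(self):
        # 100 pA for 50 ms after a single shock -> 5 pA*s
        n = 10_000
        trace = np.zeros(n)
        trace[700:1200] = 100.0
        rec = Recording(Protocol.SYNAPTIC, trace[None, :],
                        [{"isi_ms": 300.0, "shock_times_ms": [50.0], "n_samples": n}])
        q = synaptic_charge_curve(rec)
        assert q.loc[300.0] == pytest.approx(5.0, rel=0.01)

    def test_charge_curve_matches_generator(self, quiet_params, quiet_cell):
        q = synaptic_charge_curve(quiet_cell[Protocol.SYNAPTIC])
        expected = synaptic_charge(quiet_params, q.index.to_numpy())
        np.testing.assert_allclose(q.to_numpy(), expected, rtol=0.05)

    def test_no_facilitation_flat_charge(self):
        p = CellModelParams(syn_facil=0.0, noise_sd=0.0)
        q = synaptic_charge_curve(simulate_synaptic_protocol(p))
        assert np.ptp(q.to_numpy()) < 0.05 * q.mean()

    def test_ppf_round_trip(self, quiet_params, quiet_features):
        # generator facilitation 0.8 -> paired-pulse ratio 1.8
        assert 1.6 <= quiet_features["Synaptic PPF"] <= 2.0

    def test_resonance_at_facilitation_optimum(self, quiet_params, quiet_features):
        assert quiet_features["Synaptic resonance"] == pytest.approx(
            quiet_params.syn_tau, rel=0.15)


class TestMonosynapticity:
    def test_equal_windows_ratio_one(self):
        n = 6000
        trace = np.zeros(n)
        trace[100:5900] = 20.0  # constant current across both windows
        rec = Recording(Protocol.SYNAPTIC, trace[None, :],
                        [{"isi_ms": 300.0, "shock_times_ms": [10.0], "n_samples": n}])
        assert monosynapticity(rec) == pytest.approx(1.0, abs=0.05)

    def test_mono_only_cell_ratio_large(self, quiet_cell):
        assert monosynapticity(quiet_cell[Protocol.SYNAPTIC]) >= 10.0

    def test_poly_dominated_cell_ratio_small(self):
        p = CellModelParams(poly_amp=50.0, syn_amp=0.05, syn_facil=0.0, noise_sd=0.0)
        ratio = monosynapticity(simulate_synaptic_protocol(p))
        assert ratio < 0.5


class TestMinis:
    def test_injected_events_counted_and_sized(self):
        p = CellModelParams(mini_rate=1.0, mini_amp=12.0, noise_sd=2.0, seed=8)
        from ephyscensus.simulate import simulate_spontaneous
        freq, amp = detect_minis(simulate_spontaneous(p))
        assert freq == pytest.approx(1.0, abs=0.2)
        assert amp == pytest.approx(12.0, abs=1.5)

    def test_amplitude_scales_linearly(self):
        from ephyscensus.simulate import simulate_spontaneous
        amps = []
        for mini_amp in (12.0, 24.0):
            p = CellModelParams(mini_rate=1.0, mini_amp=mini_amp, noise_sd=2.0, seed=8)
            _, amp = detect_minis(simulate_spontaneous(p))
            amps.append(amp)
        assert amps[1] / amps[0] == pytest.approx(2.0, rel=0.1)


class TestAssembly:
    def test_full_quiet_cell_measures_all_33(self, quiet_features):
        assert quiet_features.n_measured == 33

    def test_missing_protocol_blanks_its_variables_only(self, quiet_cell):
        subset = {k: v for k, v in quiet_cell.items() if k != Protocol.SPONTANEOUS}
        feats = extract_all(subset)
        missing = {n for n in VARIABLE_NAMES if not np.isfinite(feats[n])}
        assert missing == {"Minis frequency", "Minis amplitude"}

    def test_no_protocols_warns_all_missing(self):
        with pytest.warns(UserWarning):
            feats = extract_all({})
        assert feats.n_measured == 0

    def test_series_round_trip_preserves_names(self, quiet_features):
        s = quiet_features.to_series()
        assert list(s.index) == VARIABLE_NAMES
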