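"""Generator calibration, determinism, and treatment-effect fidelity."""

import numpy as np
import pytest
from scipy import signal, stats

from meascreen.io import PlateLayout
from meascreen.simulate import (
    DIV27,
    StimProtocol,
    TreatmentEffect,
    WaveformModel,
    WellActivityParams,
    apply_treatment,
    render_voltage,
    simulate_ocat_session,
    simulate_spike_trains,
    simulate_temperature_ramp,
    simulate_well_trains,
)


class TestSpikeTrainGeneration:
    def test_zero_process_is_empty(self, one_well_layout):
        p = WellActivityParams(baseline_rate=0.0, burst_rate=0.0)
        trains, _ = simulate_spike_trains(one_well_layout, p, 60.0, seed=0)
        assert trains.n_spikes == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            WellActivityParams(baseline_rate=-1.0)

    def test_poisson_rate_calibration(self):
        # 3 Hz nominal over 100 electrodes x 300 s: realized mean within
        # 3 standard errors of nominal.
        layout = PlateLayout("t", n_wells=1, electrodes_per_well=100)
        p = WellActivityParams(
            baseline_rate=3.0, burst_rate=0.0, rate_cv=0.0, fraction_active=1.0
        )
        trains, _ = simulate_spike_trains(layout, p, 300.0, seed=4)
        rates = np.array([ts.size / 300.0 for ts in trains.trains.values()])
        se = np.sqrt(3.0 / 300.0) / np.sqrt(100)
        assert abs(rates.mean() - 3.0) < 3 * se

    def test_seeded_determinism(self, one_well_layout, poisson_params):
        a, _ = simulate_spike_trains(one_well_layout, poisson_params, 30.0, seed=9)
        b, _ = simulate_spike_trains(one_well_layout, poisson_params, 30.0, seed=9)
        for k in a.trains:
            np.testing.assert_array_equal(a.trains[k], b.trains[k])

    def test_adding_wells_preserves_existing_substreams(self, poisson_params):
        small = PlateLayout("t", n_wells=2, electrodes_per_well=4)
        big = PlateLayout("t", n_wells=4, electrodes_per_well=4)
        a, _ = simulate_spike_trains(small, poisson_params, 30.0, seed=9)
        b, _ = simulate_spike_trains(big, poisson_params, 30.0, seed=9)
        for k, ts in a.trains.items():
            np.testing.assert_array_equal(ts, b.trains[k])

    def test_min_isi_enforced(self, one_well_layout):
        p = WellActivityParams(baseline_rate=50.0, burst_rate=0.0, rate_cv=0.0)
        trains, _ = simulate_spike_trains(one_well_layout, p, 60.0, seed=1)
        for ts in trains.trains.values():
            if ts.size > 1:
                assert np.min(np.diff(ts)) >= 0.001 - 1e-12

    def test_div27_preset_anchors(self):
        # Shipped mature-plate preset: MFR distribution around ~3.55 Hz
        # (interval containment, not equality) over several seeds.
        from meascreen.metrics import auncc, well_mfr

        mfrs, syncs = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            trains, _ = simulate_well_trains(DIV27, 16, 300.0, rng)
            mfrs.append(well_mfr(trains, 300.0))
            syncs.append(auncc(trains, 300.0))
        assert 2.5 < np.mean(mfrs) < 4.6  # 3.55 +- ~1 Hz
        assert 0.3 <= np.mean(syncs) <= 0.6


class TestVoltageRendering:
    def test_noise_floor_sd(self):
        wf = WaveformModel(noise_sd=2.0)
        from meascreen.io import SpikeTrainSet

        empty = SpikeTrainSet({("A1", 0): np.empty(0)}, duration=10.0)
        rec = render_voltage(empty, wf, fs=12500.0, seed=0)
        sd = rec.traces.std()
        assert abs(sd - 2.0) / 2.0 < 0.02

    def test_single_spike_superposition(self):
        from meascreen.io import SpikeTrainSet

        wf = WaveformModel(amplitude=20.0, noise_sd=1e-9, jitter_cv=0.0)
        one = SpikeTrainSet({("A1", 0): np.array([0.5])}, duration=1.0)
        rec = render_voltage(one, wf, fs=12500.0, seed=0)
        peak_idx = np.argmax(np.abs(rec.traces[0]))
        assert abs(np.abs(rec.traces[0]).max() - 20.0) < 1e-6
        assert abs(peak_idx / 12500.0 - 0.5) < 0.001

    def test_template_charge_balanced(self):
        wf = WaveformModel()
        tmpl, _ = wf.template(12500.0)
        assert abs(tmpl.sum()) < 1e-9 * np.abs(tmpl).max() * tmpl.size

    def test_matched_filter_recovers_spike_times(self, spike_matcher):
        # Cross-correlating the rendered trace with the template peaks at
        # the ground-truth times.
        from meascreen.io import SpikeTrainSet

        rng = np.random.default_rng(3)
        ts = np.sort(rng.uniform(0.1, 59.9, 60))
        ts = ts[np.r_[True, np.diff(ts) > 0.01]]
        wf = WaveformModel(amplitude=12.0, noise_sd=1.5)
        trains = SpikeTrainSet({("A1", 0): ts}, duration=60.0)
        rec = render_voltage(trains, wf, fs=12500.0, seed=4)
        tmpl, peak = wf.template(12500.0)
        mf = signal.correlate(rec.traces[0], tmpl, mode="same")
        thr = 0.5 * mf.max()
        peaks, _ = signal.find_peaks(mf, height=thr, distance=13)
        found = (peaks - (len(tmpl) // 2 - peak)) / 12500.0
        tp = spike_matcher(ts, found, tol=0.001)
        assert tp / ts.size > 0.95


class TestTreatmentEffects:
    def test_null_effect_preserves_isi_distribution(self, one_well_layout,
                                                    poisson_params):
        trains, _ = simulate_spike_trains(one_well_layout, poisson_params,
                                          120.0, seed=5)
        treated, _ = apply_treatment(trains, TreatmentEffect(rate_factor=1.0),
                                     t_add=60.0, seed=6)
        key = ("A1", 0)
        np.testing.assert_array_equal(trains.trains[key], treated.trains[key])

    def test_full_block_silences_after_addition(self, one_well_layout,
                                                poisson_params):
        eff = TreatmentEffect(rate_factor=0.0, onset_tau=0.0)
        trains, _ = simulate_spike_trains(one_well_layout, poisson_params,
                                          120.0, seed=5)
        treated, _ = apply_treatment(trains, eff, t_add=60.0, seed=6)
        for ts in treated.trains.values():
            assert not np.any(ts >= 60.0)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError, match="rate_factor"):
            TreatmentEffect(rate_factor=-0.5)

    def test_dos_matches_rate_integration_oracle(self, poisson_params):
        # Oracle: integrate r(t) analytically over the treatment epoch and
        # compute DoS from expected counts.
        from meascreen.screening import dos

        factor, tau, t_add, T = 1.45, 10.0, 300.0, 600.0
        eff = TreatmentEffect(rate_factor=factor, onset_tau=tau)
        # expected post-epoch mean multiplier
        span = T - t_add
        onset_integral = span - tau * (1 - np.exp(-span / tau))
        exp_mult = 1 + (factor - 1) * onset_integral / span
        expected_dos = (exp_mult - 1) / (exp_mult + 1)

        layout = PlateLayout("t", n_wells=1, electrodes_per_well=64)
        vals = []
        for seed in range(5):
            trains, _ = simulate_spike_trains(layout, poisson_params, T, seed=seed)
            treated, _ = apply_treatment(trains, eff, t_add=t_add, seed=seed + 100)
            pre = sum(ts[ts < t_add].size for ts in treated.trains.values())
            post = sum(ts[ts >= t_add].size for ts in treated.trains.values())
            vals.append(dos(pre, post))
        assert expected_dos > 0
        assert abs(np.mean(vals) - expected_dos) < 0.02


class TestOcatSession:
    def _band_power(self, x, fs):
        f, p = signal.welch(x, fs=fs, nperseg=4096)
        sel = (f >= 100) & (f <= 600)
        return np.trapezoid(p[sel], f[sel])

    def test_no_stimulated_set_adds_no_band_power(self):
        proto = StimProtocol()
        rec, pulses = simulate_ocat_session(2, proto, stimulated=set(),
                                            noise_sd=1.5, seed=0)
        fs = rec.fs
        for row in range(2):
            post = np.concatenate([
                rec.traces[row][int((t + 0.2) * fs): int((t + 1.4) * fs)]
                for t in pulses
            ])
            pre = rec.traces[row][: int(40 * fs)]
            ratio = self._band_power(post, fs) / self._band_power(pre, fs)
            assert 0.9 < ratio < 1.1

    def test_stimulated_electrode_band_power_beats_baseline(self):
        proto = StimProtocol(response_amplitude_uv=10.0)
        rec, pulses = simulate_ocat_session(2, proto, stimulated={0},
                                            noise_sd=1.5, seed=1)
        fs = rec.fs
        wins = 0
        for t in pulses:
            post = rec.traces[0][int((t + 0.1) * fs): int((t + 1.4) * fs)]
            pre = rec.traces[0][int((t - 1.4) * fs): int((t - 0.1) * fs)]
            if self._band_power(post, fs) > self._band_power(pre, fs):
                wins += 1
        assert wins >= 9

    def test_seeded_determinism(self):
        proto = StimProtocol()
        a, _ = simulate_ocat_session(2, proto, {0}, 1.5, seed=3)
        b, _ = simulate_ocat_session(2, proto, {0}, 1.5, seed=3)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_interval_must_fit_response(self):
        with pytest.raises(ValueError, match="interval"):
            StimProtocol(interval_s=1.0, response_duration_s=1.5)


class TestTemperatureRamp:
    def test_null_gain_matches_false_positive_oracle(self):
        # gain 1: flagged fraction should match the max-bin rule's false
        # positive rate on two independent Poisson epochs (binned oracle).
        from meascreen.screening import responsiveness

        p = WellActivityParams(baseline_rate=2.0, burst_rate=0.0, rate_cv=0.0)
        flags = []
        for seed in range(4):
            trains, truth = simulate_temperature_ramp(
                p, 32, responder_fraction=1.0, gain_per_deg=1.0, seed=seed
            )
            b0, b1 = truth["baseline_epoch"]
            r0, r1 = truth["ramp_epoch"]
            for ts in trains.trains.values():
                base = ts[(ts >= b0) & (ts < b1)] - b0
                ramp = ts[(ts >= r0) & (ts < r1)] - r0
                flags.append(
                    responsiveness(base, ramp, b1 - b0, r1 - r0,
                                   mode="temperature")
                )
        measured = np.mean(flags)

        rng = np.random.default_rng(99)
        oracle = []
        n_base, n_ramp, lam = 10, 9, 2.0 * 30
        for _ in range(2000):
            base = rng.poisson(lam, n_base)
            ramp = rng.poisson(lam, n_ramp)
            oracle.append(ramp.max() >= 2 * max(base.max(), 1))
        rate = np.mean(oracle)
        se = 3 * np.sqrt(rate * (1 - rate) / len(flags) + 1e-6)
        assert abs(measured - rate) < max(se, 0.03)

    def test_strong_responders_flagged_nonresponders_not(self):
        from meascreen.screening import responsiveness

        # gain 1.35/deg: rate x4.5 by 42 C on responders
        p = WellActivityParams(baseline_rate=2.0, burst_rate=0.0, rate_cv=0.0)
        trains, truth = simulate_temperature_ramp(
            p, 64, responder_fraction=0.5, gain_per_deg=1.35, seed=21
        )
        b0, b1 = truth["baseline_epoch"]
        r0, r1 = truth["ramp_epoch"]
        flags = {}
        for (w, e), ts in trains.trains.items():
            base = ts[(ts >= b0) & (ts < b1)] - b0
            ramp = ts[(ts >= r0) & (ts < r1)] - r0
            flags[e] = responsiveness(base, ramp, b1 - b0, r1 - r0,
                                      mode="temperature")
        resp = truth["responders"]
        flagged_resp = np.mean([flags[e] for e in range(64) if resp[e]])
        flagged_non = np.mean([flags[e] for e in range(64) if not resp[e]])
        assert flagged_resp >= 0.9
        assert flagged_non <= 0.1

    def test_zero_responder_fraction_is_null(self):
        p = WellActivityParams(baseline_rate=2.0, burst_rate=0.0, rate_cv=0.0)
        trains, truth = simulate_temperature_ramp(
            p, 16, responder_fraction=0.0, gain_per_deg=1.35, seed=2
        )
        assert not truth["responders"].any()
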