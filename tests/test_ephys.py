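"""Current-clamp feature extraction: spike detection, passive properties, AP shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l4census.ephys import (
    Sweep,
    SweepSet,
    adaptation_index,
    detect_spikes,
    extract_features,
    first_ap_features,
    max_spike_count,
    membrane_tau,
    read_sweep_table,
    resting_and_input_resistance,
    rheobase,
    sag_ratio,
    write_sweep_table,
)
from l4census.synthetic import EphysCellParams, gen_sweep_set

from conftest import flat_sweep, make_sweep, single_sweep_set

DT = 1e-4


def _inject_ap(v, t_idx, thr_rise=60.0, rise_ms=0.5, fall_ms=1.0, dt=DT):
    """Stereotyped triangular AP starting at sample t_idx."""
    nr = int(round(rise_ms / 1000 / dt))
    nf = int(round(fall_ms / 1000 / dt))
    base = v[t_idx]
    v[t_idx : t_idx + nr + 1] = base + np.linspace(0, thr_rise, nr + 1)
    v[t_idx + nr + 1 : t_idx + nr + nf + 1] = base + np.linspace(thr_rise, 0, nf + 1)[1:]
    return v


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert len(detect_spikes(flat_sweep())) == 0

    def test_three_injected_waveforms_detected_at_their_times(self):
        v = np.full(10001, -70.0)
        for ms in (250, 350, 450):
            _inject_ap(v, int(ms / 1000 / DT))
        sw = make_sweep(v, current=100.0)
        train = detect_spikes(sw)
        assert len(train) == 3
        np.testing.assert_allclose(train.spike_times, [0.25, 0.35, 0.45], atol=1e-3)
        np.testing.assert_allclose(train.threshold_voltages, -70.0, atol=0.5)

    def test_slow_subthreshold_ramp_ignored(self):
        # 5 mV over 600 ms is ~0.01 mV/ms, far below the criterion
        t = np.arange(0, 1.0, DT)
        v = -70.0 + np.clip((t - 0.15) / 0.6, 0, 1) * 5.0
        sw = make_sweep(v, current=50.0)
        assert len(detect_spikes(sw)) == 0

    def test_small_peak_excursion_rejected(self):
        v = np.full(10001, -70.0)
        _inject_ap(v, 2500, thr_rise=30.0)  # peaks at -40 mV, below the -20 floor
        assert len(detect_spikes(make_sweep(v, current=100.0))) == 0

    def test_nonuniform_grid_rejected(self):
        t = np.concatenate([np.arange(0, 0.5, DT), np.arange(0.5, 1.0, 2 * DT)])
        with pytest.raises(ValueError, match="uniform"):
            Sweep(time=t, voltage=np.full(t.size, -70.0), current_pA=0.0, onset_s=0.15, offset_s=0.4)


class TestPassiveProperties:
    def test_fixed_protocol_single_sweep_ratio(self, step_response_sweep):
        ss = single_sweep_set(step_response_sweep)
        rmp, rin = resting_and_input_resistance(ss)
        assert rmp == pytest.approx(-70.0, abs=0.01)
        assert rin == pytest.approx(100.0, rel=0.01)  # -10 mV / -100 pA

    def test_variable_protocol_noiseless_line(self):
        # V_ss = -70 + 0.1 * I exactly
        sweeps = []
        for i_pa in (-100, -80, -60, -40, -20):
            v = np.full(10001, -70.0)
            stim = slice(1500, 7500)
            v[stim] = -70.0 + 0.1 * i_pa
            sweeps.append(make_sweep(v, current=float(i_pa)))
        ss = SweepSet(sweeps=tuple(sweeps), protocol="variable_holding")
        rmp, rin = resting_and_input_resistance(ss)
        assert rmp == pytest.approx(-70.0, abs=1e-6)
        assert rin == pytest.approx(100.0, rel=1e-6)

    def test_variable_protocol_rejects_gross_outlier(self):
        sweeps = []
        for i_pa in (-100, -80, -60, -40, -20):
            v = np.full(10001, -70.0)
            level = -70.0 + 0.1 * i_pa
            if i_pa == -60:
                level -= 25.0  # gross outlier
            v[1500:7500] = level
            sweeps.append(make_sweep(v, current=float(i_pa)))
        ss = SweepSet(sweeps=tuple(sweeps), protocol="variable_holding")
        _, rin = resting_and_input_resistance(ss)
        assert rin == pytest.approx(100.0, rel=0.01)

    def test_no_hyperpolarizing_sweeps_flags_missing(self):
        v = np.full(10001, -70.0)
        ss = single_sweep_set(make_sweep(v, current=20.0))
        rmp, rin = resting_and_input_resistance(ss)
        assert np.isfinite(rmp) and np.isnan(rin)

    def test_tau_recovered_from_exact_exponential(self, step_response_sweep):
        ss = single_sweep_set(step_response_sweep)
        assert membrane_tau(ss) == pytest.approx(20.0, rel=0.02)

    def test_tau_median_across_sweeps(self):
        sweeps = []
        for i_pa, tau in zip((-140, -120, -100), (0.018, 0.020, 0.022)):
            t = np.arange(0, 1.0, DT)
            v = np.full(t.size, -70.0)
            stim = (t >= 0.15) & (t <= 0.75)
            v[stim] = -70.0 - 10.0 * (1 - np.exp(-(t[stim] - 0.15) / tau))
            v[t > 0.75] = v[stim][-1]
            sweeps.append(make_sweep(v, current=float(i_pa)))
        ss = SweepSet(sweeps=tuple(sweeps))
        assert membrane_tau(ss) == pytest.approx(20.0, rel=0.02)

    def test_tau_with_noise_within_ten_percent(self, rng, step_response_sweep):
        v = step_response_sweep.voltage + rng.normal(0, 0.2, step_response_sweep.voltage.size)
        sw = make_sweep(v, current=-100.0)
        assert membrane_tau(single_sweep_set(sw)) == pytest.approx(20.0, rel=0.10)

    def test_sag_ratio_from_known_deflections(self):
        t = np.arange(0, 1.0, DT)
        v = np.full(t.size, -70.0)
        stim = (t >= 0.15) & (t <= 0.75)
        ts = t[stim] - 0.15
        # fast approach to -90 (peak), relaxation to -80 (steady)
        d = 20.0 * (1 - np.exp(-ts / 0.01))
        late = ts > 0.08
        d[late] = 10.0 + 10.0 * np.exp(-(ts[late] - 0.08) / 0.05)
        v[stim] = -70.0 - d
        v[t > 0.75] = v[stim][-1]
        ss = single_sweep_set(make_sweep(v, current=-100.0))
        assert sag_ratio(ss) == pytest.approx(2.0, rel=0.02)

    def test_monotone_approach_gives_ratio_one(self, step_response_sweep):
        assert sag_ratio(single_sweep_set(step_response_sweep)) == pytest.approx(1.0, abs=0.01)


def _fi_sweep_set(counts_by_current, silent_currents=(20.0, 40.0)):
    """Sweeps with the requested number of evenly spread in-window APs."""
    sweeps = []
    for i_pa in silent_currents:
        sweeps.append(flat_sweep(current=float(i_pa)))
    for i_pa, n in sorted(counts_by_current.items()):
        v = np.full(10001, -60.0)
        times = np.linspace(0.2, 0.7, max(n, 1), endpoint=False)
        for ts in times[:n]:
            _inject_ap(v, int(round(ts / DT)))
        sweeps.append(make_sweep(v, current=float(i_pa)))
    return SweepSet(sweeps=tuple(sweeps))


class TestRheobase:
    def test_exact_line_intercept_inside_bracket(self):
        counts = {60: 2, 80: 6, 100: 10, 120: 14, 140: 18}  # 0.2*(I-50)
        ss = _fi_sweep_set(counts, silent_currents=(40.0,))
        assert rheobase(ss) == pytest.approx(50.0, abs=0.5)

    def test_clamped_to_bracket_edge(self):
        # counts 10, 12 at 100, 120 -> line crosses far left of the bracket
        ss = _fi_sweep_set({100: 10, 120: 12}, silent_currents=(90.0,))
        assert rheobase(ss) == pytest.approx(90.0)

    def test_no_spiking_sweep_is_missing(self):
        ss = _fi_sweep_set({}, silent_currents=(20.0, 40.0))
        assert np.isnan(rheobase(ss))

    def test_noisy_counts_stay_inside_bracket(self, rng):
        true_line = {i: max(0, int(round(0.2 * (i - 50) + rng.normal(0, 0.7)))) for i in
                     (60, 80, 100, 120, 140)}
        true_line = {i: n for i, n in true_line.items() if n > 0}
        ss = _fi_sweep_set(true_line, silent_currents=(40.0,))
        est = rheobase(ss)
        assert 40.0 <= est <= min(true_line)


class TestFirstAPFeatures:
    def _ap_sweep(self, latency_s=0.12):
        dt = DT
        v = np.full(10001, -60.0)
        i0 = int(round((0.15 + latency_s) / dt))
        # piecewise linear: rise 1 ms to +20, fall 2 ms back to threshold,
        # then 1 ms further down to the -55 mV trough, then recovery
        thr, peak, trough = -40.0, 20.0, -55.0
        v[: i0 + 1] = np.linspace(-60.0, thr, i0 + 1)  # slow ramp to threshold
        nr, nf, nd = int(1e-3 / dt), int(2e-3 / dt), int(1e-3 / dt)
        v[i0 : i0 + nr + 1] = np.linspace(thr, peak, nr + 1)
        v[i0 + nr : i0 + nr + nf + 1] = np.linspace(peak, thr, nf + 1)
        v[i0 + nr + nf : i0 + nr + nf + nd + 1] = np.linspace(thr, trough, nd + 1)
        nrec = 400
        end = i0 + nr + nf + nd
        v[end : end + nrec] = trough + (np.arange(nrec) / nrec) * (-60.0 - trough + 10)
        v[end + nrec :] = -55.0
        return single_sweep_set(make_sweep(v, current=100.0))

    def test_piecewise_linear_ap_geometry(self):
        # ramp slope to threshold is shallow; dV/dt criterion fires at the kink
        thr, amp, width, ahp, adp, lat = first_ap_features(self._ap_sweep())
        assert thr == pytest.approx(-40.0, abs=0.5)
        assert amp == pytest.approx(60.0, abs=0.5)
        # half height -10 mV: 0.5 ms on the rise + 1.0 ms on the fall
        assert width == pytest.approx(1.5, abs=0.1)
        assert ahp == pytest.approx(15.0, abs=0.5)
        assert adp == pytest.approx(0.0, abs=0.5)
        assert lat == pytest.approx(120.0, abs=1.0)

    def test_latency_matches_construction(self):
        *_, lat = first_ap_features(self._ap_sweep(latency_s=0.2))
        assert lat == pytest.approx(200.0, abs=1.0)

    def test_truncated_ap_flagged_missing(self):
        v = np.full(10001, -60.0)
        v[-60:] = np.linspace(-60.0, 20.0, 60)  # rise continuing into the trace end
        ss = single_sweep_set(make_sweep(v, current=100.0, offset=0.999))
        assert all(np.isnan(x) for x in first_ap_features(ss))


class TestTrainStatistics:
    def _train_sweep(self, times_ms, current=100.0):
        v = np.full(10001, -60.0)
        for ms in times_ms:
            _inject_ap(v, int(round(ms / 1000 / DT)))
        return make_sweep(v, current=current)

    def test_regular_train_has_unit_adaptation(self):
        ss = single_sweep_set(self._train_sweep([200, 300, 400, 500]))
        assert adaptation_index(ss) == pytest.approx(1.0, abs=0.01)

    def test_isi_ratio_of_single_qualifying_sweep(self):
        ss = single_sweep_set(self._train_sweep([250, 270, 310]))
        assert adaptation_index(ss) == pytest.approx(2.0, abs=0.02)

    def test_median_over_qualifying_sweeps(self):
        sweeps = [
            self._train_sweep([200, 300, 400], current=80.0),  # AI 1
            self._train_sweep([200, 250, 350], current=100.0),  # AI 2
            self._train_sweep([200, 220, 300], current=120.0),  # AI 4
        ]
        ss = SweepSet(sweeps=tuple(sweeps))
        assert adaptation_index(ss) == pytest.approx(2.0, abs=0.02)

    def test_max_count_zero_without_spikes(self):
        assert max_spike_count(single_sweep_set(flat_sweep(current=100.0))) == 0

    def test_max_over_sweeps(self):
        sweeps = [
            self._train_sweep(np.linspace(200, 700, n, endpoint=False), current=c)
            for c, n in [(60.0, 3), (80.0, 17), (100.0, 12)]
        ]
        assert max_spike_count(SweepSet(sweeps=tuple(sweeps))) == 17

    def test_rebound_spikes_after_offset_excluded(self):
        v = np.full(10001, -60.0)
        for ms in (200, 300, 400, 500, 600):  # 5 in the window
            _inject_ap(v, int(round(ms / 1000 / DT)))
        for ms in (800, 850):  # 2 after stimulus offset (0.75 s)
            _inject_ap(v, int(round(ms / 1000 / DT)))
        ss = single_sweep_set(make_sweep(v, current=100.0))
        assert max_spike_count(ss) == 5


class TestInvariances:
    @settings(max_examples=10, deadline=None)
    @given(dt_shift=st.floats(-5.0, 5.0), dv_shift=st.floats(-20.0, 20.0))
    def test_time_shift_and_voltage_offset(self, dt_shift, dv_shift):
        ss, _ = gen_sweep_set(seed=11)
        shifted = SweepSet(
            sweeps=tuple(
                Sweep(
                    time=s.time + dt_shift,
                    voltage=s.voltage + dv_shift,
                    current_pA=s.current_pA,
                    onset_s=s.onset_s + dt_shift,
                    offset_s=s.offset_s + dt_shift,
                )
                for s in ss
            ),
            protocol=ss.protocol,
        )
        f0 = extract_features(ss).as_series()
        f1 = extract_features(shifted).as_series()
        # RMP and threshold shift with voltage; everything else is invariant
        assert f1["resting_potential"] == pytest.approx(f0["resting_potential"] + dv_shift, abs=1e-6)
        assert f1["ap_threshold"] == pytest.approx(f0["ap_threshold"] + dv_shift, abs=1e-6)
        for k in ("input_resistance", "rheobase", "ap_amplitude", "ap_width", "ahp",
                  "latency", "adaptation_index", "max_spike_count", "tau", "sag_ratio"):
            assert f1[k] == pytest.approx(f0[k], rel=1e-6), k

    def test_rheobase_always_inside_bracket(self):
        from l4census.ephys import _spike_trains, _window_count

        for seed in range(5):
            ss, truth = gen_sweep_set(seed=seed + 50)
            est = rheobase(ss)
            trains = _spike_trains(ss)
            spiking = [s.current_pA for s, tr in zip(ss, trains) if s.current_pA > 0 and _window_count(s, tr)]
            silent = [s.current_pA for s, tr in zip(ss, trains) if _window_count(s, tr) == 0 and s.current_pA < min(spiking)]
            assert (max(silent) if silent else 0) <= est <= min(spiking)


class TestIO:
    def test_sweep_table_round_trip(self, tmp_path):
        ss, _ = gen_sweep_set(seed=3, currents=np.array([-100.0, -40.0, 120.0]))
        path = tmp_path / "sweeps.csv"
        write_sweep_table(ss, path)
        back = read_sweep_table(path)
        assert len(back) == len(ss)
        for a, b in zip(ss, back):
            np.testing.assert_allclose(a.voltage, b.voltage)
            assert a.current_pA == b.current_pA

    def test_extract_features_marks_missing(self):
        ss = single_sweep_set(flat_sweep(current=-100.0))
        f = extract_features(ss)
        assert "rheobase" in f.missing and np.isnan(f.rheobase)
        assert "adaptation_index" in f.missing
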