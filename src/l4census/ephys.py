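"""Current-clamp feature extraction.

A cell is recorded as a ladder of 600-ms square current steps (typically
starting at -100 or -200 pA and increasing in 20 pA increments). Thirteen
features summarize the passive membrane properties and the firing pattern:

==================  =====  =====================================================
feature             unit   definition
==================  =====  =====================================================
resting_potential   mV     median pre-stimulus voltage (fixed holding) or the
                           intercept of a robust V_ss(I) regression (variable
                           holding)
input_resistance    MOhm   median deflection/current ratio over hyperpolarizing
                           steps (fixed holding) or the robust regression slope
                           (variable holding)
rheobase            pA     x-intercept of a robust f-I line over the five lowest
                           spiking currents, clamped to the silent/spiking
                           bracket
ap_threshold        mV     voltage at the dV/dt criterion crossing of the first
                           action potential
ap_amplitude        mV     first-AP peak minus threshold
ap_width            ms     first-AP width at half amplitude
ahp                 mV     after-hyperpolarization depth: threshold minus the
                           post-spike trough
adp                 mV     after-depolarization: first post-trough hump above
                           the trough (0 when absent)
latency             ms     first spike time minus stimulus onset
adaptation_index    --     median ISI2/ISI1 over the five lowest currents with
                           at least three spikes
max_spike_count     --     maximum number of spikes inside the stimulus window
tau                 ms     membrane time constant of the onset decay of
                           hyperpolarizing steps (median across steps)
sag_ratio           --     peak/steady-state deflection on the most
                           hyperpolarizing step
==================  =====  =====================================================

Missing features are reported as NaN and listed in
:attr:`EphysFeatures.missing`; they are never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from ._robust import consensus_line_fit

__all__ = [
    "Sweep",
    "SweepSet",
    "SpikeTrain",
    "EphysFeatures",
    "FEATURE_NAMES",
    "detect_spikes",
    "resting_and_input_resistance",
    "rheobase",
    "first_ap_features",
    "adaptation_index",
    "max_spike_count",
    "membrane_tau",
    "sag_ratio",
    "extract_features",
    "read_sweep_table",
    "write_sweep_table",
]

FEATURE_NAMES = (
    "resting_potential",
    "input_resistance",
    "rheobase",
    "ap_threshold",
    "ap_amplitude",
    "ap_width",
    "ahp",
    "adp",
    "latency",
    "adaptation_index",
    "max_spike_count",
    "tau",
    "sag_ratio",
)

#: default spike criterion: upward dV/dt crossing, minimum peak, merge window
DVDT_THRESHOLD = 20.0  # mV/ms
MIN_PEAK = -20.0  # mV
REFRACTORY_MS = 1.0
#: pre-onset window used for the baseline estimate and steady-state window
BASELINE_MS = 100.0
STEADY_STATE_MS = 100.0
#: light boxcar applied before subthreshold (non-spike) measurements
SMOOTH_MS = 3.0


@dataclass(frozen=True)
class Sweep:
    """One voltage response to a square current step.

    time is in seconds on a uniform grid; voltage in mV; current_pA is the
    step amplitude; the stimulus occupies [onset_s, offset_s].
    """

    time: np.ndarray
    voltage: np.ndarray
    current_pA: float
    onset_s: float
    offset_s: float

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and voltage must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError("sweep too short")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform and increasing")
        if not (t[0] <= self.onset_s < self.offset_s <= t[-1] + dt[0] / 2):
            raise ValueError("stimulus window must lie inside the recorded interval")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "voltage", v)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def _index(self, t: float) -> int:
        return int(round((t - self.time[0]) / self.dt))

    @property
    def onset_index(self) -> int:
        return self._index(self.onset_s)

    @property
    def offset_index(self) -> int:
        return min(self._index(self.offset_s), self.time.size - 1)

    def smoothed(self, window_ms: float = SMOOTH_MS) -> np.ndarray:
        n = max(1, int(round(window_ms / 1000.0 / self.dt)))
        if n % 2 == 0:
            n += 1
        return uniform_filter1d(self.voltage, n, mode="nearest")

    def baseline(self) -> float:
        """Median voltage over the 100 ms preceding stimulus onset."""
        i1 = self.onset_index
        i0 = max(0, i1 - int(round(BASELINE_MS / 1000.0 / self.dt)))
        if i1 <= i0:
            raise ValueError("no pre-stimulus samples")
        return float(np.median(self.voltage[i0:i1]))

    def steady_state(self) -> float:
        """Mean raw voltage over the last 100 ms before stimulus offset.

        The 100 ms average suppresses noise by itself; smoothing first would
        bleed post-offset samples across the stimulus edge.
        """
        i1 = self.offset_index
        i0 = max(self.onset_index, i1 - int(round(STEADY_STATE_MS / 1000.0 / self.dt)))
        return float(np.mean(self.voltage[i0:i1]))


@dataclass(frozen=True)
class SweepSet:
    """A cell's sweeps in order of strictly increasing step current."""

    sweeps: tuple[Sweep, ...]
    protocol: str = "fixed_holding"  # or "variable_holding"

    def __post_init__(self):
        sw = tuple(self.sweeps)
        if not sw:
            raise ValueError("empty sweep set")
        amps = [s.current_pA for s in sw]
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("current amplitudes must be strictly increasing")
        if self.protocol not in ("fixed_holding", "variable_holding"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        object.__setattr__(self, "sweeps", sw)

    def __iter__(self):
        return iter(self.sweeps)

    def __len__(self):
        return len(self.sweeps)

    def hyperpolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.current_pA < 0]

    def depolarizing(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.current_pA > 0]


@dataclass(frozen=True)
class SpikeTrain:
    """Detected action potentials of one sweep."""

    spike_times: np.ndarray  # s, at the dV/dt threshold crossing
    threshold_voltages: np.ndarray  # mV
    peak_voltages: np.ndarray  # mV
    threshold_indices: np.ndarray
    peak_indices: np.ndarray
    truncated_last: bool = False  # last AP peak coincides with the trace end

    def __len__(self):
        return int(self.spike_times.size)

    def in_window(self, t0: float, t1: float) -> int:
        return int(np.count_nonzero((self.spike_times >= t0) & (self.spike_times <= t1)))


@dataclass
class EphysFeatures:
    """The 13 extracted features; missing values are NaN and named in ``missing``."""

    resting_potential: float = np.nan
    input_resistance: float = np.nan
    rheobase: float = np.nan
    ap_threshold: float = np.nan
    ap_amplitude: float = np.nan
    ap_width: float = np.nan
    ahp: float = np.nan
    adp: float = np.nan
    latency: float = np.nan
    adaptation_index: float = np.nan
    max_spike_count: float = np.nan
    tau: float = np.nan
    sag_ratio: float = np.nan
    missing: set = field(default_factory=set)

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self) if f.name != "missing"})

    def mark_missing(self, *names: str):
        for name in names:
            setattr(self, name, np.nan)
            self.missing.add(name)


# ---------------------------------------------------------------------------
# spike detection


def detect_spikes(
    sweep: Sweep,
    dvdt_threshold: float = DVDT_THRESHOLD,
    min_peak: float = MIN_PEAK,
    refractory_ms: float = REFRACTORY_MS,
) -> SpikeTrain:
    """Detect action potentials by an upward dV/dt criterion crossing.

    One spike is emitted per contiguous suprathreshold excursion: the
    threshold is the voltage at the first sample where dV/dt crosses
    ``dvdt_threshold`` upward, the peak is the local voltage maximum before
    repolarization below the threshold voltage. Excursions whose peak stays
    below ``min_peak`` are rejected, and crossings within ``refractory_ms``
    of a previous spike's peak are merged into it.
    """
    if dvdt_threshold <= 0:
        raise ValueError("dvdt_threshold must be positive")
    v = sweep.voltage
    dt_ms = sweep.dt * 1000.0
    dvdt = np.gradient(v) / dt_ms
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1

    refr = int(round(refractory_ms / dt_ms))
    times, thrs, peaks, t_idx, p_idx = [], [], [], [], []
    truncated = False
    last_peak = -10**9
    for c in crossings:
        if c - last_peak <= refr:
            continue
        thr_v = v[c]
        # end of the excursion: first repolarization below the threshold voltage
        below = np.flatnonzero(v[c + 1 :] < thr_v)
        end = c + 1 + below[0] if below.size else v.size
        pk = c + int(np.argmax(v[c:end]))
        if v[pk] < min_peak:
            continue
        if pk >= v.size - 1 and not below.size:
            truncated = True
        last_peak = pk
        times.append(sweep.time[c])
        thrs.append(thr_v)
        peaks.append(v[pk])
        t_idx.append(c)
        p_idx.append(pk)
    return SpikeTrain(
        spike_times=np.asarray(times),
        threshold_voltages=np.asarray(thrs),
        peak_voltages=np.asarray(peaks),
        threshold_indices=np.asarray(t_idx, dtype=int),
        peak_indices=np.asarray(p_idx, dtype=int),
        truncated_last=truncated,
    )


def _spike_trains(sweeps: SweepSet) -> list[SpikeTrain]:
    return [detect_spikes(s) for s in sweeps]


def _window_count(sweep: Sweep, train: SpikeTrain) -> int:
    return train.in_window(sweep.onset_s, sweep.offset_s)


# ---------------------------------------------------------------------------
# passive properties


def resting_and_input_resistance(sweeps: SweepSet) -> tuple[float, float]:
    """Resting membrane potential (mV) and input resistance (MOhm).

    Fixed holding: the resting potential is the median pre-stimulus voltage
    pooled across sweeps, and the input resistance the median per-sweep
    ratio of the steady-state deflection to the injected current over
    hyperpolarizing sweeps. Variable holding: both come from a robust
    (exhaustive-consensus) regression of the steady-state voltage on the
    injected current over the five most hyperpolarizing sweeps — slope is
    the resistance, intercept the resting potential.

    Returns NaN for features that cannot be computed.
    """
    hyper = sweeps.hyperpolarizing()
    if sweeps.protocol == "fixed_holding":
        pre = []
        for s in sweeps:
            i1 = s.onset_index
            i0 = max(0, i1 - int(round(BASELINE_MS / 1000.0 / s.dt)))
            pre.append(s.voltage[i0:i1])
        rmp = float(np.median(np.concatenate(pre)))
        if not hyper:
            return rmp, np.nan
        ratios = [(s.steady_state() - s.baseline()) / s.current_pA for s in hyper]
        rin = float(np.median(ratios)) * 1000.0  # mV/pA = GOhm -> MOhm
        return rmp, rin

    # variable holding
    if len({s.current_pA for s in hyper}) < 2:
        return np.nan, np.nan
    sel = sorted(hyper, key=lambda s: s.current_pA)[:5]
    x = np.array([s.current_pA for s in sel])
    y = np.array([s.steady_state() for s in sel])
    slope, intercept = consensus_line_fit(x, y)
    return float(intercept), float(slope) * 1000.0


def membrane_tau(sweeps: SweepSet) -> float:
    """Membrane time constant (ms): median exponential fit over hyperpolarizing sweeps.

    Per sweep, ``V(t) = a + b exp(-(t - onset)/tau)`` is fit by nonlinear
    least squares over the first phase of the hyperpolarization, from
    stimulus onset to the time of the voltage minimum, with a log-linear
    initialization.
    """
    taus = []
    for s in sweeps.hyperpolarizing():
        v = s.smoothed()
        i0, i2 = s.onset_index, s.offset_index
        imin = i0 + int(np.argmin(v[i0:i2]))
        if imin - i0 < 5:
            continue
        t = (s.time[i0 : imin + 1] - s.time[i0]) * 1000.0  # ms
        y = v[i0 : imin + 1]
        a0 = y[-1]
        b0 = y[0] - a0
        if abs(b0) < 1e-9:
            continue
        # log-linear initialization on the first two thirds of the decay
        z = (y - a0) / b0
        ok = z > 1e-3
        tau0 = 20.0
        if ok.sum() > 3:
            slope, _ = np.polyfit(t[ok], np.log(z[ok]), 1)
            if slope < 0:
                tau0 = -1.0 / slope
        try:
            popt, _ = curve_fit(
                lambda tt, a, b, tau: a + b * np.exp(-tt / tau),
                t,
                y,
                p0=[a0, b0, tau0],
                bounds=([-200.0, -200.0, 0.01], [100.0, 200.0, 1000.0]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        taus.append(popt[2])
    return float(np.median(taus)) if taus else np.nan


def sag_ratio(sweeps: SweepSet) -> float:
    """Peak-to-steady-state deflection ratio on the most hyperpolarizing sweep."""
    hyper = sweeps.hyperpolarizing()
    if not hyper:
        return np.nan
    s = min(hyper, key=lambda s: s.current_pA)
    base = s.baseline()
    v = s.smoothed()
    peak_defl = base - float(np.min(v[s.onset_index : s.offset_index]))
    steady_defl = base - s.steady_state()
    if abs(steady_defl) < 1e-9:
        return np.nan
    return peak_defl / steady_defl


# ---------------------------------------------------------------------------
# firing properties


def rheobase(sweeps: SweepSet, trains: list[SpikeTrain] | None = None) -> float:
    """Rheobase (pA): robust f-I line intercept clamped to the silent/spiking bracket.

    Spike counts within the stimulus window of the five lowest depolarizing
    currents with non-zero count are regressed on the current; the line's
    x-intercept is the estimate. It is restricted to lie between the highest
    current eliciting no spikes and the lowest current eliciting at least
    one spike; if the line crosses outside, the nearest bracket edge is
    taken.
    """
    trains = trains if trains is not None else _spike_trains(sweeps)
    counts = {s.current_pA: _window_count(s, tr) for s, tr in zip(sweeps, trains)}
    spiking = sorted(i for i, c in counts.items() if c > 0 and i > 0)
    if not spiking:
        return np.nan
    lo_spiking = spiking[0]
    silent = [i for i, c in counts.items() if c == 0 and i < lo_spiking]
    hi_silent = max(silent) if silent else 0.0
    sel = spiking[:5]
    if len(sel) < 2:
        return lo_spiking
    x = np.array(sel)
    y = np.array([counts[i] for i in sel], dtype=float)
    slope, intercept = consensus_line_fit(x, y)
    if slope <= 0:
        return lo_spiking
    est = -intercept / slope
    return float(np.clip(est, hi_silent, lo_spiking))


def first_ap_features(
    sweeps: SweepSet, trains: list[SpikeTrain] | None = None
) -> tuple[float, float, float, float, float, float]:
    """(threshold mV, amplitude mV, width ms, AHP mV, ADP mV, latency ms) of the first AP.

    Measured on the very first action potential fired by the neuron, i.e.
    the first spike of the lowest-current sweep that spikes. The width is
    taken at half amplitude with linear interpolation of the crossings; the
    AHP is the depth of the post-spike trough below threshold; the ADP is
    the height of the first post-trough hump above the trough within 10 ms
    (zero when absent). A truncated AP (peak at the trace end) yields NaNs.
    """
    nan6 = (np.nan,) * 6
    trains = trains if trains is not None else _spike_trains(sweeps)
    for s, tr in zip(sweeps, trains):
        if s.current_pA <= 0 or _window_count(s, tr) == 0:
            continue
        if len(tr) == 1 and tr.truncated_last:
            return nan6
        v = s.voltage
        thr_i = int(tr.threshold_indices[0])
        pk_i = int(tr.peak_indices[0])
        thr_v = float(tr.threshold_voltages[0])
        pk_v = float(tr.peak_voltages[0])
        amplitude = pk_v - thr_v
        half = thr_v + amplitude / 2.0

        def _cross_time(i0, i1, level, rising):
            seg = v[i0 : i1 + 1]
            if rising:
                idx = np.flatnonzero(seg >= level)
            else:
                idx = np.flatnonzero(seg <= level)
            if not idx.size:
                return np.nan
            j = i0 + idx[0]
            if j == i0:
                return s.time[j]
            frac = (level - v[j - 1]) / (v[j] - v[j - 1])
            return s.time[j - 1] + frac * s.dt

        t_up = _cross_time(thr_i, pk_i, half, rising=True)
        # falling flank: search until the next spike or 100 ms past the peak
        stop = int(tr.threshold_indices[1]) if len(tr) > 1 else min(
            pk_i + int(round(0.1 / s.dt)), s.offset_index
        )
        stop = max(stop, pk_i + 2)
        t_down = _cross_time(pk_i, min(stop, v.size - 1), half, rising=False)
        if np.isnan(t_up) or np.isnan(t_down):
            return nan6
        width = (t_down - t_up) * 1000.0

        trough_stop = min(stop, v.size - 1)
        tr_rel = int(np.argmin(v[pk_i : trough_stop + 1]))
        trough_i = pk_i + tr_rel
        trough_v = float(v[trough_i])
        ahp = thr_v - trough_v

        # ADP: first depolarizing hump above the trough within 10 ms of it.
        # Candidate humps are found on the smoothed trace with a 0.5 mV
        # prominence floor (a monotone recovery has none); the amplitude is
        # read off the raw trace against the raw trough.
        adp = 0.0
        adp_stop = min(trough_i + int(round(0.010 / s.dt)), trough_stop)
        # lighter smoothing than for subthreshold measures: the hump is only
        # a few ms wide and must survive the filter
        seg = s.smoothed(1.0)[trough_i : adp_stop + 1]
        if seg.size >= 5:
            from scipy.signal import find_peaks

            pk_loc, _ = find_peaks(seg, prominence=0.5)
            if pk_loc.size:
                j = trough_i + int(pk_loc[0])
                w = int(round(0.001 / s.dt))
                raw_max = float(v[max(j - w, pk_i) : min(j + w + 1, v.size)].max())
                adp = max(0.0, raw_max - trough_v)

        latency = (tr.spike_times[0] - s.onset_s) * 1000.0
        return thr_v, amplitude, width, ahp, adp, float(latency)
    return nan6


def adaptation_index(sweeps: SweepSet, trains: list[SpikeTrain] | None = None) -> float:
    """Median ISI2/ISI1 over the five lowest currents eliciting >= 3 spikes."""
    trains = trains if trains is not None else _spike_trains(sweeps)
    ais = []
    for s, tr in zip(sweeps, trains):
        if s.current_pA <= 0:
            continue
        t = tr.spike_times[(tr.spike_times >= s.onset_s) & (tr.spike_times <= s.offset_s)]
        if t.size < 3:
            continue
        isi1, isi2 = t[1] - t[0], t[2] - t[1]
        if isi1 > 0:
            ais.append(isi2 / isi1)
        if len(ais) == 5:
            break
    return float(np.median(ais)) if ais else np.nan


def max_spike_count(sweeps: SweepSet, trains: list[SpikeTrain] | None = None) -> int:
    """Maximum number of spikes within the stimulus window over all sweeps."""
    trains = trains if trains is not None else _spike_trains(sweeps)
    return max((_window_count(s, tr) for s, tr in zip(sweeps, trains)), default=0)


# ---------------------------------------------------------------------------
# driver


def extract_features(sweeps: SweepSet) -> EphysFeatures:
    """Extract all 13 features from a sweep set; missing ones are flagged."""
    trains = _spike_trains(sweeps)
    f = EphysFeatures()
    rmp, rin = resting_and_input_resistance(sweeps)
    f.resting_potential, f.input_resistance = rmp, rin
    f.rheobase = rheobase(sweeps, trains)
    (f.ap_threshold, f.ap_amplitude, f.ap_width, f.ahp, f.adp, f.latency) = first_ap_features(
        sweeps, trains
    )
    f.adaptation_index = adaptation_index(sweeps, trains)
    f.max_spike_count = float(max_spike_count(sweeps, trains))
    f.tau = membrane_tau(sweeps)
    f.sag_ratio = sag_ratio(sweeps)
    for name in FEATURE_NAMES:
        if np.isnan(getattr(f, name)):
            f.missing.add(name)
    return f


# ---------------------------------------------------------------------------
# file I/O: long-format delimited table


def write_sweep_table(sweeps: SweepSet, path) -> None:
    """Write a sweep set as a long-format CSV (one row per sample).

    Columns: sweep_id, time_s, voltage_mV, current_pA, onset_s, offset_s.
    """
    frames = []
    for k, s in enumerate(sweeps):
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": k,
                    "time_s": s.time,
                    "voltage_mV": s.voltage,
                    "current_pA": s.current_pA,
                    "onset_s": s.onset_s,
                    "offset_s": s.offset_s,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_sweep_table(path, protocol: str = "fixed_holding") -> SweepSet:
    """Read a long-format sweep CSV written by :func:`write_sweep_table`."""
    df = pd.read_csv(path)
    sw = []
    for _, g in df.groupby("sweep_id", sort=True):
        sw.append(
            Sweep(
                time=g["time_s"].to_numpy(),
                voltage=g["voltage_mV"].to_numpy(),
                current_pA=float(g["current_pA"].iloc[0]),
                onset_s=float(g["onset_s"].iloc[0]),
                offset_s=float(g["offset_s"].iloc[0]),
            )
        )
    sw.sort(key=lambda s: s.current_pA)
    return SweepSet(sweeps=tuple(sw), protocol=protocol)
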