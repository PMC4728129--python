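"""Extraction of the 33 electrophysiological variables from a cell's recordings.

Variables by canonical index:

====  =========================  =====
#     name                       unit
====  =========================  =====
1     Cm                         pF
2     Rm                         GOhm
3     Ra                         MOhm
4     I hold                     pA
5     I_Na activation            mV
6     I_Na                       pA
7     I_KS activation            mV
8     I_KS                       pA
9     I_KT activation            mV
10    I_KT                       pA
11    Tail                       ms
12    Spike threshold            mV
13    Spike amplitude            mV
14    Spike rise-time            ms
15    Spike width                ms
16    I best                     pA
17    N spikes step              spikes
18    Spike ISI                  ms
19    Spike ISI accommodation    ratio (ISI2/ISI1)
20    Spike accommodation        ratio (amp2/amp1)
21    N spikes cosine            spikes/wave
22    Spiking resonance          ms
23    Spiking resonance width    ms
24    Wave buildup               wave #
25    Wave decay                 waves
26    Jitter                     ln units (<= 0)
27    Synaptic resonance         ms
28    Synaptic resonance width   ms
29    Synaptic charge            pA*s
30    Synaptic PPF               ratio
31    Monosynapticity            ratio
32    Minis frequency            Hz
33    Minis amplitude            pA
====  =========================  =====

Passive variables #1-#4 come from the seal test (recording metadata); every
other variable is computed from the traces. Missing protocols yield missing
values, never errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import fits
from .model import Protocol, Recording
from .spikes import DetectorConfig, SpikeTrain, detect_spikes, jitter_index

VARIABLES: list[tuple[int, str, str]] = [
    (1, "Cm", "pF"), (2, "Rm", "GOhm"), (3, "Ra", "MOhm"), (4, "I hold", "pA"),
    (5, "I_Na activation", "mV"), (6, "I_Na", "pA"),
    (7, "I_KS activation", "mV"), (8, "I_KS", "pA"),
    (9, "I_KT activation", "mV"), (10, "I_KT", "pA"),
    (11, "Tail", "ms"), (12, "Spike threshold", "mV"),
    (13, "Spike amplitude", "mV"), (14, "Spike rise-time", "ms"),
    (15, "Spike width", "ms"), (16, "I best", "pA"),
    (17, "N spikes step", "spikes"), (18, "Spike ISI", "ms"),
    (19, "Spike ISI accommodation", "ratio"), (20, "Spike accommodation", "ratio"),
    (21, "N spikes cosine", "spikes/wave"), (22, "Spiking resonance", "ms"),
    (23, "Spiking resonance width", "ms"), (24, "Wave buildup", "wave"),
    (25, "Wave decay", "waves"), (26, "Jitter", "ln"),
    (27, "Synaptic resonance", "ms"), (28, "Synaptic resonance width", "ms"),
    (29, "Synaptic charge", "pA*s"), (30, "Synaptic PPF", "ratio"),
    (31, "Monosynapticity", "ratio"), (32, "Minis frequency", "Hz"),
    (33, "Minis amplitude", "pA"),
]

VARIABLE_NAMES = [name for _, name, _ in VARIABLES]


@dataclass
class ExtractionConfig:
    """Windows and thresholds of the extraction stage (all times in ms)."""

    # IV windows; the early/steady windows sit inside the 150 ms step
    iv_early_ms: tuple[float, float] = (0.0, 18.5)
    iv_steady_ms: tuple[float, float] = (116.5, 136.5)
    # synaptic windows (relative to each shock)
    artifact_blank_ms: float = 4.0
    mono_window_ms: tuple[float, float] = (5.0, 14.0)
    poly_window_ms: tuple[float, float] = (15.0, 145.0)
    long_isi_min_ms: float = 100.0
    charge_window_ms: float = 300.0   # integration extent past the last shock
    # mEPSC detector
    mini_min_amp_pa: float = 5.0
    mini_threshold_mads: float = 4.5
    mini_min_spacing_ms: float = 5.0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    # accommodation orientation: ISI2/ISI1 and amp2/amp1
    isi_accom_order: tuple[int, int] = (1, 0)
    amp_accom_order: tuple[int, int] = (1, 0)


@dataclass
class CellFeatures:
    """The 33 named variables of one cell; unmeasured variables are NaN."""

    cell_id: str = "cell"
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {name: np.nan for name in VARIABLE_NAMES}
        full.update(self.values)
        self.values = full

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.cell_id)

    @property
    def n_measured(self) -> int:
        return int(np.sum(np.isfinite(list(self.values.values()))))


# ---------------------------------------------------------------------------
# IV protocol
# ---------------------------------------------------------------------------

def measure_iv_currents(rec: Recording, config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Windowed per-step current measurements from a passive-subtracted IV series.

    I_Na = minimum over the early window (negative peak); I_K_peak = maximum
    over the early window; I_KS = mean over the steady window; and
    I_KT = I_K_peak - I_KS by definition.
    """
    config = config or ExtractionConfig()
    dt = 1000.0 / rec.fs
    e0, e1 = (int(round(w / dt)) for w in config.iv_early_ms)
    s0, s1 = (int(round(w / dt)) for w in config.iv_steady_ms)
    if rec.sweeps.shape[1] < s1:
        raise ValueError("IV sweep shorter than the steady-state window")
    rows = []
    for sweep, stim in zip(rec.sweeps, rec.stimulus):
        early = sweep[e0:e1 + 1]
        steady = sweep[s0:s1 + 1]
        i_na = float(np.min(early))
        i_k_peak = float(np.max(early))
        i_ks = float(np.mean(steady))
        rows.append({"v": stim["command_mv"], "i_na": i_na, "i_k_peak": i_k_peak,
                     "i_ks": i_ks, "i_kt": i_k_peak - i_ks})
    return pd.DataFrame(rows)


def iv_features(rec: Recording, config: ExtractionConfig | None = None) -> dict[str, float]:
    """Variables #5-#10 from the IV-step recording."""
    table = measure_iv_currents(rec, config)
    out: dict[str, float] = {}
    na = fits.fit_iv_sigmoid(table["v"], table["i_na"])
    if na.converged:
        out["I_Na activation"] = na.derived["half_act"]
        out["I_Na"] = na.derived["i_max"]
    ks = fits.fit_iv_ks(table["v"], table["i_ks"])
    if ks.converged:
        out["I_KS activation"] = ks.derived["act"]
        out["I_KS"] = ks.derived["i_max"]
    kt = fits.fit_iv_sigmoid(table["v"], table["i_kt"])
    if kt.converged:
        out["I_KT activation"] = kt.derived["half_act"]
        out["I_KT"] = kt.derived["i_max"]
    return out


# ---------------------------------------------------------------------------
# Step protocol
# ---------------------------------------------------------------------------

def _tail_tau(sweep: np.ndarray, off_ms: float, fs: float) -> float:
    """Exponential time constant of post-injection repolarization (log-linear fit)."""
    dt = 1000.0 / fs
    i0 = int(round((off_ms + 1.0) / dt))
    i1 = min(sweep.size, int(round((off_ms + 150.0) / dt)))
    if i1 - i0 < 20:
        return np.nan
    seg = sweep[i0:i1]
    v_inf = float(np.median(sweep[max(i0, i1 - int(20 / dt)):i1]))
    dev = seg - v_inf
    sign = np.sign(dev[0]) if dev[0] != 0 else 1.0
    y = sign * dev
    keep = y > max(0.05 * y[0], 1e-6)
    if keep.sum() < 10:
        return np.nan
    t = np.arange(seg.size)[keep] * dt
    slope, _ = np.polyfit(t, np.log(y[keep]), 1)
    return float(-1.0 / slope) if slope < 0 else np.nan


def step_trains(rec: Recording, config: ExtractionConfig | None = None) -> list[SpikeTrain]:
    config = config or ExtractionConfig()
    return [detect_spikes(sweep, rec.fs, config.detector, sweep_id=k)
            for k, sweep in enumerate(rec.sweeps)]


def step_train_features(rec: Recording, trains: list[SpikeTrain] | None = None,
                        config: ExtractionConfig | None = None) -> dict[str, float]:
    """Variables #11-#20 from the step-current recording."""
    config = config or ExtractionConfig()
    if trains is None:
        trains = step_trains(rec, config)
    currents = np.array([s["current_pa"] for s in rec.stimulus])
    counts = np.array([tr.n_spikes for tr in trains], dtype=float)
    out: dict[str, float] = {}
    # tail: median repolarization time constant across sweeps
    taus = [_tail_tau(sweep, s["onset_ms"] + s["duration_ms"], rec.fs)
            for sweep, s in zip(rec.sweeps, rec.stimulus)]
    taus = [t for t in taus if np.isfinite(t)]
    if taus:
        out["Tail"] = float(np.median(taus))
    # spikes-vs-current fit -> I best, N spikes step
    fit = fits.fit_spikes_vs_current(currents, counts)
    if counts.max() == 0:
        out["N spikes step"] = 0.0
    elif fit.converged:
        out["I best"] = fit.derived["argmax"]
        out["N spikes step"] = fit.derived["max"]
    # shape of the first spike at the smallest spiking current
    spiking = [k for k, tr in enumerate(trains) if tr.n_spikes > 0]
    if spiking:
        first = trains[spiking[int(np.argmin(currents[spiking]))]]
        out["Spike threshold"] = float(first.kink_potentials[0])
        out["Spike amplitude"] = float(first.amplitudes[0])
        out["Spike rise-time"] = float(first.rise_times[0])
        out["Spike width"] = float(first.half_widths[0])
        # train dynamics from the sweep with most spikes, closest to I best
        best_i = out.get("I best", currents[spiking[-1]])
        top = counts.max()
        cand = [k for k in spiking if counts[k] == top]
        train = trains[cand[int(np.argmin(np.abs(currents[cand] - best_i)))]]
        isis = train.isis()
        i1, i0 = config.isi_accom_order
        if isis.size >= 1:
            out["Spike ISI"] = float(isis[0])
        if isis.size >= 2:
            out["Spike ISI accommodation"] = float(isis[i1] / isis[i0])
        if train.n_spikes >= 2:
            a1, a0 = config.amp_accom_order
            out["Spike accommodation"] = float(train.amplitudes[a1] / train.amplitudes[a0])
    return out


# ---------------------------------------------------------------------------
# Cosine protocol
# ---------------------------------------------------------------------------

def cosine_wave_counts(rec: Recording, trains: list[SpikeTrain] | None = None,
                       config: ExtractionConfig | None = None):
    """Per-period mean spikes-per-wave and per-wave counts at the shortest period.

    Returns (periods, per-wave means, wave_counts_100hz averaged over sweeps,
    trains).
    """
    config = config or ExtractionConfig()
    if trains is None:
        trains = [detect_spikes(sweep, rec.fs, config.detector, sweep_id=k)
                  for k, sweep in enumerate(rec.sweeps)]
    stim = rec.stimulus[0]
    periods = np.asarray(stim["periods_ms"], dtype=float)
    starts = np.asarray(stim["bout_starts_ms"], dtype=float)
    bout_ms = float(stim["bout_ms"])
    per_wave = np.zeros(periods.size)
    shortest = int(np.argmin(periods))
    n_waves_short = int(round(bout_ms / periods[shortest]))
    wave_counts = np.zeros(n_waves_short)
    for tr in trains:
        for b, (start, T) in enumerate(zip(starts, periods)):
            n_waves = int(round(bout_ms / T))
            in_bout = tr.spike_times[(tr.spike_times >= start)
                                     & (tr.spike_times < start + bout_ms)]
            per_wave[b] += in_bout.size / n_waves
            if b == shortest and in_bout.size:
                idx = np.clip(((in_bout - start) // T).astype(int), 0, n_waves - 1)
                np.add.at(wave_counts, idx, 1.0)
    n_sweeps = max(len(trains), 1)
    return periods, per_wave / n_sweeps, wave_counts / n_sweeps, trains


def cosine_features(rec: Recording, config: ExtractionConfig | None = None) -> dict[str, float]:
    """Variables #21-#26 from the cosine-injection recording."""
    config = config or ExtractionConfig()
    periods, per_wave, wave_counts, trains = cosine_wave_counts(rec, None, config)
    out: dict[str, float] = {}
    out["N spikes cosine"] = float(np.mean(per_wave))
    if per_wave.max() > 0:
        fit = fits.fit_cosine_tuning(periods, per_wave)
        if fit.converged:
            out["Spiking resonance"] = fit.derived["argmax"]
            out["Spiking resonance width"] = fit.params["b"]
    if wave_counts.max() > 0:
        wfit = fits.fit_wave_train(np.arange(1, wave_counts.size + 1), wave_counts)
        if wfit.converged:
            out["Wave buildup"] = wfit.derived["argmax"]
            out["Wave decay"] = wfit.params["c"]
    jit = jitter_index(trains, duration_ms=rec.sweeps.shape[1] * 1000.0 / rec.fs)
    if np.isfinite(jit):
        out["Jitter"] = jit
    return out


# ---------------------------------------------------------------------------
# Synaptic protocol
# ---------------------------------------------------------------------------

def _sweep_view(rec: Recording, k: int) -> np.ndarray:
    n = rec.stimulus[k].get("n_samples", rec.sweeps.shape[1])
    return rec.sweeps[k, :n]


def _blank_artifacts(trace: np.ndarray, shocks_ms, blank_ms: float, fs: float) -> np.ndarray:
    """Replace each artifact window by linear interpolation across it, so
    underlying synaptic current spanning a shock is approximately kept."""
    out = trace.copy()
    dt = 1000.0 / fs
    for sh in shocks_ms:
        i0 = max(0, int(round(sh / dt)) - 1)
        i1 = min(out.size, int(round((sh + blank_ms) / dt)))
        if i1 <= i0:
            continue
        left = out[i0 - 1] if i0 > 0 else 0.0
        right = out[i1] if i1 < out.size else 0.0
        out[i0:i1] = np.linspace(left, right, i1 - i0 + 2)[1:-1]
    return out


def synaptic_charge_curve(rec: Recording, config: ExtractionConfig | None = None) -> pd.Series:
    """Total synaptic charge (pA*s) per inter-stimulus interval.

    Stimulation artifacts are blanked, the repeats of each ISI are averaged,
    the baseline (pre-stimulus median) is subtracted, and current is
    integrated from the first shock to `charge_window_ms` past the last one.
    """
    config = config or ExtractionConfig()
    dt_s = 1.0 / rec.fs
    groups: dict[float, list[int]] = {}
    for k, s in enumerate(rec.stimulus):
        groups.setdefault(float(s["isi_ms"]), []).append(k)
    charges = {}
    for isi in sorted(groups):
        idx = groups[isi]
        shocks = rec.stimulus[idx[0]]["shock_times_ms"]
        n = min(rec.stimulus[k].get("n_samples", rec.sweeps.shape[1]) for k in idx)
        avg = np.mean([_sweep_view(rec, k)[:n] for k in idx], axis=0)
        avg = _blank_artifacts(avg, shocks, config.artifact_blank_ms, rec.fs)
        pre = avg[: max(1, int(round((shocks[0] - 5.0) * rec.fs / 1000.0)))]
        avg = avg - float(np.median(pre))
        i0 = int(round(shocks[0] * rec.fs / 1000.0))
        i1 = min(n, int(round((shocks[-1] + config.charge_window_ms) * rec.fs / 1000.0)))
        charges[isi] = float(np.sum(avg[i0:i1]) * dt_s)
    return pd.Series(charges).sort_index()


def monosynapticity(rec: Recording, config: ExtractionConfig | None = None) -> float:
    """Ratio of mean current in the monosynaptic (5-14 ms) window to the
    polysynaptic (15-145 ms) window, over long-ISI sweeps.

    Larger values mean a more purely monosynaptic response. The poly window
    is truncated at the next shock for stimuli that are not last in the
    train. Returns NaN when the poly-window mean is indistinguishable
    from zero.
    """
    config = config or ExtractionConfig()
    dt = 1000.0 / rec.fs
    groups: dict[float, list[int]] = {}
    for k, s in enumerate(rec.stimulus):
        if float(s["isi_ms"]) >= config.long_isi_min_ms:
            groups.setdefault(float(s["isi_ms"]), []).append(k)
    if not groups:
        return np.nan
    mono_vals, poly_vals = [], []
    for isi, idx in groups.items():
        shocks = rec.stimulus[idx[0]]["shock_times_ms"]
        n = min(rec.stimulus[k].get("n_samples", rec.sweeps.shape[1]) for k in idx)
        avg = np.mean([_sweep_view(rec, k)[:n] for k in idx], axis=0)
        avg = _blank_artifacts(avg, shocks, config.artifact_blank_ms, rec.fs)
        pre = avg[: max(1, int(round((shocks[0] - 5.0) / dt)))]
        avg = avg - float(np.median(pre))
        for j, sh in enumerate(shocks):
            m0 = int(round((sh + config.mono_window_ms[0]) / dt))
            m1 = int(round((sh + config.mono_window_ms[1]) / dt))
            p_end = config.poly_window_ms[1]
            if j < len(shocks) - 1:
                p_end = min(p_end, isi - config.artifact_blank_ms)
            p0 = int(round((sh + config.poly_window_ms[0]) / dt))
            p1 = int(round((sh + p_end) / dt))
            if m1 <= avg.size and p1 <= avg.size and p1 > p0:
                mono_vals.append(float(np.mean(avg[m0:m1])))
                poly_vals.append(float(np.mean(avg[p0:p1])))
    if not mono_vals:
        return np.nan
    mono, poly = np.mean(mono_vals), np.mean(poly_vals)
    scale = max(np.std(poly_vals), abs(mono), 1e-12)
    if abs(poly) < 1e-3 * scale:
        return np.nan
    return float(mono / poly)


def synaptic_features(rec: Recording, config: ExtractionConfig | None = None) -> dict[str, float]:
    """Variables #27-#31 from the synaptic-stimulation recording."""
    config = config or ExtractionConfig()
    q = synaptic_charge_curve(rec, config)
    out: dict[str, float] = {}
    if len(q) >= 6:
        fit = fits.fit_synaptic_resonance(q.index.to_numpy(), q.to_numpy())
        if fit.converged:
            out["Synaptic resonance"] = fit.derived["argmax"]
            out["Synaptic resonance width"] = fit.params["c"]
            out["Synaptic charge"] = fit.derived["max"]
            if np.isfinite(fit.derived.get("ppf", np.nan)):
                out["Synaptic PPF"] = fit.derived["ppf"]
    mono = monosynapticity(rec, config)
    if np.isfinite(mono):
        out["Monosynapticity"] = mono
    return out


# ---------------------------------------------------------------------------
# Spontaneous activity
# ---------------------------------------------------------------------------

def detect_minis(rec: Recording | np.ndarray, config: ExtractionConfig | None = None,
                 fs: float = 10_000.0) -> tuple[float, float]:
    """mEPSC frequency (Hz) and mean amplitude (pA) from a spontaneous trace.

    Threshold detection on a lightly smoothed trace: events are peaks
    exceeding baseline + max(mini_min_amp, k * MAD-noise), separated by a
    refractory spacing. Returns (frequency, NaN) when no events are found.
    """
    config = config or ExtractionConfig()
    if isinstance(rec, Recording):
        trace = rec.sweeps[0]
        fs = rec.fs
        duration_s = trace.size / fs
    else:
        trace = np.asarray(rec, dtype=float)
        duration_s = trace.size / fs
    dt = 1000.0 / fs
    kernel = signal.windows.gaussian(9, std=2.0)
    kernel /= kernel.sum()
    smooth = signal.convolve(trace, kernel, mode="same")
    baseline = float(np.median(smooth))
    mad = float(np.median(np.abs(smooth - baseline))) / 0.6745
    height = baseline + max(config.mini_min_amp_pa, config.mini_threshold_mads * mad)
    distance = max(1, int(round(config.mini_min_spacing_ms / dt)))
    peaks, props = signal.find_peaks(smooth, height=height, distance=distance,
                                     prominence=max(config.mini_min_amp_pa * 0.6,
                                                    2.0 * mad))
    freq = peaks.size / duration_s
    if peaks.size == 0:
        return 0.0, np.nan
    amps = props["peak_heights"] - baseline
    return float(freq), float(np.mean(amps))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_all(recordings: dict[Protocol, Recording], cell_id: str | None = None,
                config: ExtractionConfig | None = None) -> CellFeatures:
    """Compute every variable whose protocol is present; absent ones stay NaN."""
    config = config or ExtractionConfig()
    recordings = {Protocol(k): v for k, v in recordings.items()}
    if not recordings:
        warnings.warn("no protocols supplied; all variables missing")
        return CellFeatures(cell_id=cell_id or "cell")
    if cell_id is None:
        cell_id = next(iter(recordings.values())).cell_id
    values: dict[str, float] = {}
    any_rec = next(iter(recordings.values()))
    seal = any_rec.meta.get("seal", {})
    values["Cm"] = float(seal.get("cm", np.nan))
    values["Rm"] = float(seal.get("rm", np.nan))
    values["Ra"] = float(seal.get("ra", np.nan))
    values["I hold"] = float(seal.get("i_hold", np.nan))
    if Protocol.IV_STEPS in recordings:
        values.update(iv_features(recordings[Protocol.IV_STEPS], config))
    if Protocol.CURRENT_STEPS in recordings:
        values.update(step_train_features(recordings[Protocol.CURRENT_STEPS],
                                          config=config))
    if Protocol.COSINE in recordings:
        values.update(cosine_features(recordings[Protocol.COSINE], config))
    if Protocol.SYNAPTIC in recordings:
        values.update(synaptic_features(recordings[Protocol.SYNAPTIC], config))
    if Protocol.SPONTANEOUS in recordings:
        freq, amp = detect_minis(recordings[Protocol.SPONTANEOUS], config)
        values["Minis frequency"] = freq
        if np.isfinite(amp):
            values["Minis amplitude"] = amp
    return CellFeatures(cell_id=cell_id, values=values)
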