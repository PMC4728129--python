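"""Protocol-faithful synthetic whole-cell recordings with exact ground truth.

The generator reproduces the five acquisition protocols of a tectal-cell
census (voltage-clamp IV steps, current-clamp step injections, cosine-bout
injections, paired-pulse synaptic stimulation at the optic chiasm, and a
one-minute spontaneous recording) at 10 kHz, from a phenomenological cell
model: voltage-clamp traces are built directly from the Boltzmann /
exponential-hinge IV forms the extractor fits, spiking is an adaptive
threshold-and-waveform process whose tuning curves follow the extractor's
own difference-of-exponentials and ramp-exponential forms, and synaptic
charge follows a known facilitation curve. Every one of the 33 extracted
variables therefore has an exact generative counterpart, making recovery
tests closed-form.

Generative constants (kinetic time constants, slope factors) are module
constants, not free parameters: they shape the within-window time courses
but cancel out of every extracted quantity.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .fits import diffexp, diffexp_argmax, ks_hinge, ramp_exp, sigmoid
from .model import (
    COSINE_AMP_PA, COSINE_BOUT_MS, COSINE_FREQS_HZ, COSINE_N_SWEEPS,
    CURRENT_STEPS_PA, CohortDesign, CellModelParams, Condition, DT_MS, FS_HZ,
    GroupSpec, IV_STEP_DURATION_MS, IV_STEP_POTENTIALS_MV, Protocol, Recording,
    SPONTANEOUS_DURATION_S, SYNAPTIC_ISIS_MS, SYNAPTIC_N_REPEATS,
    SYNAPTIC_N_STIMULI, StageGroup,
)

# --- IV kinetics (fixed; cancel out of extracted amplitudes) ---------------
NA_SLOPE_MV = 6.0       # Boltzmann slope of Na activation
KT_SLOPE_MV = 6.0       # Boltzmann slope of transient-K activation
KS_B_MV = 25.0          # exponential scale of the stable-K hinge
NA_DELAY_MS = 0.3       # Na current onset
NA_TAU_MS = 0.5         # Na alpha-kernel time-to-peak
K_DELAY_MS = 3.0        # K currents onset (temporally separates Na and K)
KS_TAU_MS = 1.0         # stable-K rise
KT_TAU_MS = 5.0         # transient-K alpha-kernel time-to-peak

# --- step-protocol layout ---------------------------------------------------
STEP_PRE_MS = 100.0
STEP_DUR_MS = 300.0
STEP_POST_MS = 200.0
STEP_NS_A = 10.0        # current offset of the spikes-vs-current bump, pA
STEP_NS_B = 400.0       # slow scale of the bump, pA

# --- cosine-protocol layout -------------------------------------------------
COS_PRE_MS = 100.0
COS_GAP_MS = 100.0
COS_NT_A = 5.0          # period offset of the n(T) tuning bump, ms

# --- synaptic protocol ------------------------------------------------------
SYN_PRE_MS = 50.0
SYN_POST_MS = 400.0
EPSC_TAU_MS = 2.0
EPSC_DELAY_MS = 5.2     # monosynaptic latency after the shock
ARTIFACT_PA = 3000.0
POLY_START_MS = 15.0
POLY_END_MS = 145.0

MINI_TAU_MS = 1.5


# ---------------------------------------------------------------------------
# Ground-truth tuning curves
# ---------------------------------------------------------------------------

def na_amplitude(v, p: CellModelParams):
    """Peak Na+ current (pA, negative) at command potential v."""
    return sigmoid(v, p.na_act, NA_SLOPE_MV, p.na_max, 0.0)


def kt_amplitude(v, p: CellModelParams):
    """Peak transient-K+ current (pA) at command potential v."""
    return sigmoid(v, p.kt_act, KT_SLOPE_MV, p.kt_max, 0.0)


def ks_amplitude(v, p: CellModelParams):
    """Steady-state stable-K+ current (pA); activates at exactly ks_act."""
    a = p.ks_act - KS_B_MV  # hinge opens at a + b = ks_act
    top = np.exp((max(IV_STEP_POTENTIALS_MV) - a) / KS_B_MV) - np.e
    c = p.ks_max / top if top > 0 else 0.0
    return ks_hinge(v, a, KS_B_MV, c, 0.0)


def step_tuning(p: CellModelParams) -> tuple[float, float, float, float]:
    """(a, b, c, d) of the generative spikes-vs-current curve; max = spike_gain."""
    a, b, c = STEP_NS_A, STEP_NS_B, p.spike_adapt
    peak = diffexp(diffexp_argmax(a, b, c), a, b, c, 1.0)
    return a, b, c, p.spike_gain / peak


def step_best_current(p: CellModelParams) -> float:
    """Ground-truth 'I best' (pA)."""
    a, b, c, _ = step_tuning(p)
    return diffexp_argmax(a, b, c)


def cosine_tuning(p: CellModelParams) -> tuple[float, float, float, float]:
    """(a, b, c, d) of the generative spikes-per-wave vs period curve.

    b is the requested tuning width; c is solved so the analytic argmax
    lands exactly at cos_resonance; d scales the peak to cos_gain.
    """
    a, b = COS_NT_A, p.cos_width
    target = p.cos_resonance - a
    if not (0.0 < target < b):
        raise ValueError("cos_resonance must lie in (COS_NT_A, COS_NT_A + cos_width)")
    c = brentq(lambda cc: (b * cc / (b - cc)) * np.log(b / cc) - target,
               1e-9 * b, b * (1 - 1e-9))
    peak = diffexp(p.cos_resonance, a, b, c, 1.0)
    return a, b, c, p.cos_gain / peak


def wave_profile(p: CellModelParams, n_waves: int) -> np.ndarray:
    """Relative per-wave spiking weight at 100 Hz; argmax at wave_buildup."""
    x = np.arange(1, n_waves + 1, dtype=float)
    a = p.wave_buildup - p.wave_decay
    w = ramp_exp(x, a, p.wave_buildup, p.wave_decay, 1.0, 0.0)
    w = np.maximum(w, 0.0)
    return w / w.mean() if w.mean() > 0 else np.zeros_like(w)


def synaptic_charge(p: CellModelParams, isi_ms) -> np.ndarray:
    """Ground-truth total synaptic charge per sweep (pA*s) as a function of ISI.

    Q(tau) = 5*syn_amp * (1 + syn_facil * g(tau)), with g a unit-peak bump
    at tau = syn_tau; the projected charge under infinitely slow stimulation
    is 5*syn_amp, so the ground-truth paired-pulse ratio is 1 + syn_facil.
    """
    tau = np.asarray(isi_ms, dtype=float)
    g = (tau / p.syn_tau) * np.exp(1.0 - tau / p.syn_tau)
    return SYNAPTIC_N_STIMULI * p.syn_amp * (1.0 + p.syn_facil * g)


# ---------------------------------------------------------------------------
# Waveform building blocks
# ---------------------------------------------------------------------------

def _spike_waveform(p: CellModelParams) -> tuple[np.ndarray, int]:
    """Triangular spike waveform (kink-relative, mV); returns (wave, peak idx).

    Linear rise over spike_rise/0.8 ms makes the 10-90% rise time exactly
    spike_rise; fall duration is set so the half-height width is exactly
    spike_width.
    """
    t_rise = p.spike_rise / 0.8
    t_fall = 2.0 * p.spike_width - t_rise
    n_up = max(2, int(round(t_rise / DT_MS)))
    n_down = max(2, int(round(t_fall / DT_MS)))
    up = np.linspace(0.0, 1.0, n_up + 1)
    down = np.linspace(1.0, 0.0, n_down + 1)[1:]
    return np.concatenate([up, down]), n_up


def _insert_spikes(trace: np.ndarray, times_ms: np.ndarray, amps: np.ndarray,
                   p: CellModelParams, level: float | None = None) -> None:
    """Add spike waveforms (peak-aligned at times_ms) on top of `trace` in place.

    `level` pins the kink potential (defaults to the local baseline), so the
    extracted spike threshold has exact ground truth.
    """
    wave, pk = _spike_waveform(p)
    n = trace.size
    for t, a in zip(times_ms, amps):
        start = int(round(t / DT_MS)) - pk
        if start < 0 or start + wave.size > n:
            continue
        seg = trace[start:start + wave.size]
        base = seg[0] if level is None else level
        np.maximum(seg, base + wave * a, out=seg)


def _alpha_kernel(tau_ms: float, n_samples: int) -> np.ndarray:
    """Unit-peak alpha kernel (t/tau)*exp(1 - t/tau)."""
    t = np.arange(n_samples) * DT_MS
    return (t / tau_ms) * np.exp(1.0 - t / tau_ms)


def _deterministic_counts(mu: np.ndarray) -> np.ndarray:
    """Integer per-bin counts whose running total tracks cumulative mu,
    rounding to nearest so the bout total is round(sum(mu))."""
    cum = np.floor(np.cumsum(mu) + 0.5 + 1e-9)
    return np.diff(np.concatenate([[0.0], cum])).astype(int)


def _rng(p: CellModelParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(p.seed) % (2**63), spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Protocol simulators
# ---------------------------------------------------------------------------

def simulate_iv_protocol(p: CellModelParams, seed: int | None = None,
                         **rec_kw) -> Recording:
    """Voltage-clamp step series: -65..+115 mV in 20 mV steps, 150 ms each.

    Traces are active currents only (passive component already subtracted):
    a fast transient Na+ component, a delayed sustained K+ component, and a
    delayed transient K+ component, each with unit-peak kinetics so windowed
    extraction reads off the generative amplitudes exactly.
    """
    rng = np.random.default_rng(seed) if seed is not None else _rng(p, 0)
    n = int(round(IV_STEP_DURATION_MS / DT_MS))
    t = np.arange(n) * DT_MS
    s_na = np.maximum(t - NA_DELAY_MS, 0.0)
    na_kernel = np.where(t > NA_DELAY_MS,
                         (s_na / NA_TAU_MS) * np.exp(1.0 - s_na / NA_TAU_MS), 0.0)
    s_k = np.maximum(t - K_DELAY_MS, 0.0)
    ks_kernel = np.where(t > K_DELAY_MS, 1.0 - np.exp(-s_k / KS_TAU_MS), 0.0)
    kt_kernel = np.where(t > K_DELAY_MS,
                         (s_k / KT_TAU_MS) * np.exp(1.0 - s_k / KT_TAU_MS), 0.0)
    sweeps, stim = [], []
    for v in IV_STEP_POTENTIALS_MV:
        trace = (float(na_amplitude(v, p)) * na_kernel
                 + float(ks_amplitude(v, p)) * ks_kernel
                 + float(kt_amplitude(v, p)) * kt_kernel)
        if p.noise_sd > 0:
            trace = trace + rng.normal(0.0, p.noise_sd, n)
        sweeps.append(trace)
        stim.append({"command_mv": v, "duration_ms": IV_STEP_DURATION_MS})
    return Recording(Protocol.IV_STEPS, np.array(sweeps), stim, **rec_kw)


def _step_spike_times(p: CellModelParams, n_spikes: int) -> np.ndarray:
    """Spike times within one step sweep (ms from sweep start)."""
    t0 = STEP_PRE_MS + 12.0
    isis, isi = [], p.isi_first
    for k in range(n_spikes - 1):
        isis.append(isi)
        if k < 2:  # accommodation acts on the first intervals, then saturates
            isi *= p.isi_accom
    times = t0 + np.concatenate([[0.0], np.cumsum(isis)]) if n_spikes else np.empty(0)
    return times[times < STEP_PRE_MS + STEP_DUR_MS - 5.0]


def simulate_step_protocol(p: CellModelParams, seed: int | None = None,
                           **rec_kw) -> Recording:
    """Current-clamp step series: 0..180 pA in 20 pA increments.

    Spike counts per sweep follow the generative difference-of-exponentials
    tuning; spikes are inserted as parameterized waveforms with kink at
    spike_thresh, so every shape and train variable has exact ground truth.
    The post-injection repolarization decays with tau_m = rm*cm.
    """
    rng = np.random.default_rng(seed) if seed is not None else _rng(p, 1)
    a, b, c, d = step_tuning(p)
    n = int(round((STEP_PRE_MS + STEP_DUR_MS + STEP_POST_MS) / DT_MS))
    t = np.arange(n) * DT_MS
    on, off = STEP_PRE_MS, STEP_PRE_MS + STEP_DUR_MS
    sweeps, stim = [], []
    for i in CURRENT_STEPS_PA:
        n_spk = int(round(float(diffexp(i, a, b, c, d)))) if p.spike_gain > 0 else 0
        if i <= 0:
            n_spk = 0
        # subthreshold plateau; cells that spike sit at threshold
        if n_spk > 0:
            plateau = p.spike_thresh
        else:
            depol = min(i * p.rm * 0.25, p.spike_thresh - p.e_rest - 3.0)
            plateau = p.e_rest + max(depol, 0.0)
        v = np.full(n, p.e_rest)
        # fast charging ramp (fixed 3 ms) so spikes ride a settled plateau;
        # the repolarization tail decays with the cell's own tau_m
        rise = 1.0 - np.exp(-(t - on) / 3.0)
        mask = (t >= on) & (t < off)
        v[mask] = p.e_rest + (plateau - p.e_rest) * rise[mask]
        tail = t >= off
        v[tail] = p.e_rest + (plateau - p.e_rest) * np.exp(-(t[tail] - off) / max(p.tau_m, 1.0))
        times = _step_spike_times(p, n_spk)
        amps = p.spike_amp * p.amp_accom ** np.arange(times.size)
        _insert_spikes(v, times, amps, p,
                       level=p.spike_thresh if n_spk > 0 else None)
        if p.noise_sd > 0:
            v = v + rng.normal(0.0, 0.15 * p.noise_sd, n)
        sweeps.append(v)
        stim.append({"current_pa": i, "onset_ms": on, "duration_ms": STEP_DUR_MS})
    return Recording(Protocol.CURRENT_STEPS, np.array(sweeps), stim, **rec_kw)


def simulate_cosine_protocol(p: CellModelParams, seed: int | None = None,
                             **rec_kw) -> Recording:
    """Ten repeated sweeps of five 200 ms cosine bouts (100/50/30/25/20 Hz, 135 pA).

    Per-wave spike emission follows the generative period-tuning curve; at
    100 Hz an additional per-wave buildup/decay profile shapes the counts.
    Per-sweep spike-time jitter (SD = spike_jitter) makes the jitter index
    meaningful; with noise_sd = 0 and spike_jitter = 0 all sweeps are identical.
    """
    rng = np.random.default_rng(seed) if seed is not None else _rng(p, 2)
    a, b, c, d = cosine_tuning(p)
    periods = [1000.0 / f for f in COSINE_FREQS_HZ]
    bout_starts = [COS_PRE_MS + k * (COSINE_BOUT_MS + COS_GAP_MS) for k in range(len(periods))]
    total_ms = bout_starts[-1] + COSINE_BOUT_MS + COS_GAP_MS
    n = int(round(total_ms / DT_MS))
    t = np.arange(n) * DT_MS
    # subthreshold cosine ripple under the spikes
    ripple = np.zeros(n)
    for start, T in zip(bout_starts, periods):
        m = (t >= start) & (t < start + COSINE_BOUT_MS)
        ripple[m] = 0.5 * (1.0 - np.cos(2 * np.pi * (t[m] - start) / T))
    depol = max(min(5.0, p.spike_thresh - p.e_rest - 3.0), 0.0)
    base = p.e_rest + depol * ripple
    sweeps, stim = [], []
    for sweep_i in range(COSINE_N_SWEEPS):
        v = base.copy()
        all_times, all_amps = [], []
        for start, T in zip(bout_starts, periods):
            n_waves = int(round(COSINE_BOUT_MS / T))
            mu = float(diffexp(T, a, b, c, d)) * np.ones(n_waves)
            if T == min(periods):
                mu = mu * wave_profile(p, n_waves)
            counts = _deterministic_counts(mu)
            for w, k in enumerate(counts):
                peak = start + (w + 0.35) * T
                for j in range(k):
                    tt = peak + 2.5 * j
                    if p.spike_jitter > 0:
                        tt += rng.normal(0.0, p.spike_jitter)
                    all_times.append(tt)
                    all_amps.append(p.spike_amp)
        order = np.argsort(all_times)
        _insert_spikes(v, np.asarray(all_times)[order], np.asarray(all_amps)[order], p)
        if p.noise_sd > 0:
            v = v + rng.normal(0.0, 0.15 * p.noise_sd, n)
        sweeps.append(v)
        stim.append({"bout_starts_ms": bout_starts, "periods_ms": periods,
                     "bout_ms": COSINE_BOUT_MS, "amp_pa": COSINE_AMP_PA})
    return Recording(Protocol.COSINE, np.array(sweeps), stim, **rec_kw)


def simulate_synaptic_protocol(p: CellModelParams, seed: int | None = None,
                               **rec_kw) -> Recording:
    """Optic-chiasm style paired-pulse series: 5 shocks x 10 ISIs x 5 repeats.

    Each shock leaves a brief biphasic artifact, a monosynaptic EPSC whose
    charge follows the generative facilitation curve, and (if poly_amp > 0)
    a slow polysynaptic current in the 15-145 ms window.
    """
    rng = np.random.default_rng(seed) if seed is not None else _rng(p, 3)
    kernel_n = int(round(12.0 / DT_MS))
    epsc = _alpha_kernel(EPSC_TAU_MS, kernel_n)
    epsc_unit = epsc / (epsc.sum() * (DT_MS / 1000.0))  # unit charge (1 pA*s)
    poly_n = int(round((POLY_END_MS - POLY_START_MS) / DT_MS))
    ramp = min(poly_n // 4, int(round(10.0 / DT_MS)))
    poly_shape = np.ones(poly_n)
    poly_shape[:ramp] = np.linspace(0.0, 1.0, ramp)
    poly_shape[-ramp:] = np.linspace(1.0, 0.0, ramp)
    sweeps, stim = [], []
    for rep in range(SYNAPTIC_N_REPEATS):
        for isi in SYNAPTIC_ISIS_MS:
            total = float(synaptic_charge(p, isi))
            q_first = p.syn_amp
            q_later = (total - q_first) / (SYNAPTIC_N_STIMULI - 1)
            shocks = SYN_PRE_MS + np.arange(SYNAPTIC_N_STIMULI) * isi
            n = int(round((shocks[-1] + SYN_POST_MS) / DT_MS))
            trace = np.zeros(n)
            for k, sh in enumerate(shocks):
                i0 = int(round(sh / DT_MS))
                trace[i0:i0 + 2] += ARTIFACT_PA
                trace[i0 + 2:i0 + 4] -= ARTIFACT_PA
                j0 = int(round((sh + EPSC_DELAY_MS) / DT_MS))
                q = q_first if k == 0 else q_later
                seg = epsc_unit[:max(0, min(kernel_n, n - j0))]
                trace[j0:j0 + seg.size] += q * seg
                if p.poly_amp > 0:
                    p0 = int(round((sh + POLY_START_MS) / DT_MS))
                    pseg = poly_shape[:max(0, min(poly_n, n - p0))]
                    trace[p0:p0 + pseg.size] += p.poly_amp * pseg
            if p.noise_sd > 0:
                trace = trace + rng.normal(0.0, p.noise_sd, n)
            sweeps.append(trace)
            stim.append({"isi_ms": isi, "repeat": rep,
                         "shock_times_ms": shocks.tolist()})
    max_len = max(s.size for s in sweeps)
    padded = np.zeros((len(sweeps), max_len))
    for i, s in enumerate(sweeps):
        padded[i, :s.size] = s
        stim[i]["n_samples"] = s.size
    return Recording(Protocol.SYNAPTIC, padded, stim, **rec_kw)


def simulate_spontaneous(p: CellModelParams, seed: int | None = None,
                         **rec_kw) -> Recording:
    """One-minute voltage-clamp recording of spontaneous mEPSC-like events."""
    rng = np.random.default_rng(seed) if seed is not None else _rng(p, 4)
    n = int(round(SPONTANEOUS_DURATION_S * FS_HZ))
    trace = rng.normal(0.0, p.noise_sd, n) if p.noise_sd > 0 else np.zeros(n)
    n_events = rng.poisson(p.mini_rate * SPONTANEOUS_DURATION_S) if p.mini_rate > 0 else 0
    kernel = _alpha_kernel(MINI_TAU_MS, int(round(12.0 / DT_MS)))
    starts = np.sort(rng.integers(0, n - kernel.size, size=n_events))
    amps = p.mini_amp * np.maximum(0.3, 1.0 + 0.15 * rng.standard_normal(n_events))
    for s, a in zip(starts, amps):
        trace[s:s + kernel.size] += a * kernel
    stim = [{"duration_s": SPONTANEOUS_DURATION_S, "n_events_true": int(n_events)}]
    return Recording(Protocol.SPONTANEOUS, trace[None, :], stim, **rec_kw)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

# Group distributions are configuration that qualitatively emulates the
# developmental directions of change (older naive cells more variable,
# stimulated cells spikier but less variable); they are not estimates of
# real-animal values.
_BASE_SD = {
    "cm": 2.5, "rm": 0.4, "ra": 8.0, "e_rest": 8.0,
    "na_act": 4.0, "na_max": 120.0, "ks_act": 4.0, "ks_max": 80.0,
    "kt_act": 4.0, "kt_max": 70.0,
    "spike_gain": 1.5, "spike_adapt": 12.0, "spike_thresh": 3.0,
    "spike_amp": 6.0, "spike_rise": 0.06, "spike_width": 0.15,
    "isi_first": 3.0, "isi_accom": 0.08, "amp_accom": 0.04,
    "cos_resonance": 6.0, "cos_gain": 0.2,
    "wave_buildup": 0.8, "wave_decay": 0.6,
    "syn_amp": 0.25, "syn_facil": 0.2, "syn_tau": 8.0,
    "mini_rate": 0.3, "mini_amp": 2.5,
}

DEFAULT_GROUP_SPECS: dict[tuple[StageGroup, Condition], GroupSpec] = {
    (StageGroup.S45_46, Condition.NAIVE): GroupSpec(
        n_cells=64, means={"spike_gain": 4.0}, sds=dict(_BASE_SD)),
    (StageGroup.S47, Condition.NAIVE): GroupSpec(
        n_cells=24, means={"spike_gain": 7.5}, sds=dict(_BASE_SD)),
    (StageGroup.S48_49, Condition.NAIVE): GroupSpec(
        n_cells=56, means={"spike_gain": 4.6},
        sds={k: 1.4 * v for k, v in _BASE_SD.items()}),
    (StageGroup.S48_49, Condition.STIMULATED): GroupSpec(
        n_cells=60, means={"spike_gain": 7.1, "cm": 8.0},
        sds={k: 0.8 * v for k, v in _BASE_SD.items()}),
    (StageGroup.S43_44, Condition.NAIVE): GroupSpec(
        n_cells=11, means={"spike_gain": 2.5},
        sds={k: 0.8 * v for k, v in _BASE_SD.items()}),
}

_CLIP = {
    "cm": (1.0, None), "rm": (0.2, None), "ra": (5.0, None),
    "na_max": (None, 0.0), "ks_max": (0.0, None), "kt_max": (0.0, None),
    "spike_gain": (0.0, None), "spike_adapt": (15.0, 350.0),
    "spike_rise": (0.25, None), "spike_width": (0.6, None),
    "isi_first": (6.0, None), "isi_accom": (1.0, 2.0), "amp_accom": (0.5, 1.0),
    "cos_resonance": (10.0, 55.0), "cos_gain": (0.05, None),
    "wave_buildup": (1.5, 12.0), "wave_decay": (1.0, 10.0),
    "syn_amp": (0.05, None), "syn_facil": (0.0, None), "syn_tau": (10.0, 200.0),
    "mini_rate": (0.0, None), "mini_amp": (2.0, None),
    "e_rest": (-75.0, -42.0), "spike_thresh": (-48.0, -30.0),
    "na_act": (-45.0, -20.0), "ks_act": (-35.0, -5.0), "kt_act": (-40.0, -10.0),
}


def make_cell_params(stage_group: StageGroup, condition: Condition, seed: int,
                     spec: GroupSpec | None = None) -> CellModelParams:
    """Draw one cell's ground-truth parameters from its group distribution."""
    stage_group = StageGroup(stage_group)
    condition = Condition(condition)
    if spec is None:
        key = (stage_group, condition)
        if key not in DEFAULT_GROUP_SPECS:
            raise KeyError(f"no default parameter distribution for {key}")
        spec = DEFAULT_GROUP_SPECS[key]
    rng = np.random.default_rng(seed)
    base = CellModelParams()
    values = {}
    for name in _BASE_SD:
        mean = spec.means.get(name, getattr(base, name))
        sd = spec.sds.get(name, 0.0)
        val = mean + sd * rng.standard_normal() if sd > 0 else float(mean)
        lo, hi = _CLIP.get(name, (None, None))
        if lo is not None:
            val = max(val, lo)
        if hi is not None:
            val = min(val, hi)
        values[name] = float(val)
    # keep threshold above rest and cosine resonance inside its feasible band
    values["spike_thresh"] = max(values["spike_thresh"], values["e_rest"] + 6.0)
    values["cos_resonance"] = min(values["cos_resonance"], COS_NT_A + 0.9 * base.cos_width)
    return base.replace(seed=seed, **values)


def simulate_cell(p: CellModelParams, cell_id: str = "cell",
                  stage_group: StageGroup = StageGroup.S48_49,
                  condition: Condition = Condition.NAIVE,
                  protocols: Iterable[Protocol] | None = None) -> dict[Protocol, Recording]:
    """Simulate all (or a subset of) protocols for one cell."""
    protocols = list(protocols) if protocols is not None else list(Protocol)
    kw = dict(cell_id=cell_id, stage_group=stage_group, condition=condition)
    out: dict[Protocol, Recording] = {}
    sims = {
        Protocol.IV_STEPS: simulate_iv_protocol,
        Protocol.CURRENT_STEPS: simulate_step_protocol,
        Protocol.COSINE: simulate_cosine_protocol,
        Protocol.SYNAPTIC: simulate_synaptic_protocol,
        Protocol.SPONTANEOUS: simulate_spontaneous,
    }
    seal = {"cm": p.cm, "rm": p.rm, "ra": p.ra, "i_hold": p.i_hold}
    for proto in protocols:
        rec = sims[Protocol(proto)](p, **kw)
        rec.meta["seal"] = dict(seal)
        out[proto] = rec
    return out


def iter_cohort(design: CohortDesign) -> Iterator[tuple[str, CellModelParams, dict[Protocol, Recording]]]:
    """Lazily generate (cell_id, params, recordings) for every cell of a design."""
    ss = np.random.SeedSequence(design.seed)
    for (stage, cond), spec in design.groups.items():
        children = ss.spawn(spec.n_cells) if spec.n_cells else []
        for k, child in enumerate(children):
            cell_seed = int(child.generate_state(1)[0] % (2**31))
            cid = f"{StageGroup(stage).value}_{Condition(cond).value}_{k:03d}"
            p = make_cell_params(stage, cond, cell_seed, spec)
            yield cid, p, simulate_cell(p, cid, StageGroup(stage), Condition(cond))


def make_cohort(design: CohortDesign):
    """Materialize a full cohort: (recordings dict, ground-truth table).

    For large designs prefer :func:`iter_cohort`, which streams cells.
    """
    recordings: dict[str, dict[Protocol, Recording]] = {}
    rows = []
    for cid, p, recs in iter_cohort(design):
        recordings[cid] = recs
        row = asdict(p)
        row["cell_id"] = cid
        row["stage_group"] = recs[next(iter(recs))].stage_group.value
        row["condition"] = recs[next(iter(recs))].condition.value
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("cell_id") if rows else pd.DataFrame()
    return recordings, truth


def apply_missingness(matrix: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Mask entries completely at random, never emptying a row or a column."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missingness rate must lie in [0, 1)")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    vals = out.to_numpy(dtype=float)
    mask = rng.random(vals.shape) < rate
    # guard: keep at least one observed value in every row and column
    for i in range(mask.shape[0]):
        if mask[i].all():
            mask[i, rng.integers(mask.shape[1])] = False
    for j in range(mask.shape[1]):
        if mask[:, j].all():
            mask[rng.integers(mask.shape[0]), j] = False
    vals[mask] = np.nan
    out.iloc[:, :] = vals
    return out


# ---------------------------------------------------------------------------
# Direct feature-matrix synthesis (for the statistical stages)
# ---------------------------------------------------------------------------

def synth_feature_matrix(n_cells: int, n_vars: int = 33, n_factors: int = 2,
                         loading_scale: float = 1.0, noise_sd: float = 1.0,
                         scale: float = 1.0, seed: int = 0,
                         prefix: str = "cell") -> pd.DataFrame:
    """Synthetic cells x variables matrix with a known low-rank factor structure.

    Columns are built as loadings @ factors + isotropic noise; `scale`
    multiplies the whole matrix, emulating a group with inflated
    cell-to-cell variability. Used to exercise the multivariate stages with
    known ground truth.
    """
    rng = np.random.default_rng(seed)
    load = rng.normal(0.0, loading_scale, size=(n_vars, n_factors))
    scores = rng.standard_normal((n_cells, n_factors))
    x = scores @ load.T + noise_sd * rng.standard_normal((n_cells, n_vars))
    x *= scale
    return pd.DataFrame(
        x, index=[f"{prefix}{i:03d}" for i in range(n_cells)],
        columns=[f"v{j + 1:02d}" for j in range(n_vars)])
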