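"""Nonlinear fits of IV curves and spiking/synaptic tuning curves.

Four functional families cover every tuning curve in the pipeline:

* ``sigmoid``   I(v) = c / (1 + exp(-(v - a)/b)) + d           (I_Na, I_KT IV curves)
* ``ks_hinge``  I(v) = max(0, exp((v - a)/b) - e) * c + d      (I_KS IV curve; e = Euler's number)
* ``diffexp``   f(x) = max(0, exp(-(x - a)/b) - exp(-(x - a)/c)) * d
                                                               (spikes vs current; spikes vs cosine period)
* ``ramp_exp``  f(x) = (x - a) * exp(-(x - b)/c) * d + e       (per-wave counts; synaptic charge vs ISI)

All fits use bounded nonlinear least squares with a small set of
deterministic multi-starts; derived quantities (argmax, extremum,
half-activation) are read off the fitted curve on a 0.1-unit grid spanning
the sampled range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitResult",
    "sigmoid",
    "ks_hinge",
    "diffexp",
    "ramp_exp",
    "diffexp_argmax",
    "ramp_exp_argmax",
    "fit_iv_sigmoid",
    "fit_iv_ks",
    "fit_spikes_vs_current",
    "fit_cosine_tuning",
    "fit_wave_train",
    "fit_synaptic_resonance",
]

GRID_STEP = 0.1


@dataclass
class FitResult:
    """Parameters and derived scalars of one curve fit."""

    params: dict[str, float] = field(default_factory=dict)
    derived: dict[str, float] = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = False

    def __getitem__(self, key: str) -> float:
        if key in self.params:
            return self.params[key]
        return self.derived[key]


def sigmoid(v, a, b, c, d):
    z = np.clip(-(np.asarray(v, dtype=float) - a) / b, -500, 500)
    return c / (1.0 + np.exp(z)) + d


def ks_hinge(v, a, b, c, d):
    z = np.clip((np.asarray(v, dtype=float) - a) / b, -500, 500)
    return np.maximum(0.0, np.exp(z) - np.e) * c + d


def diffexp(x, a, b, c, d):
    x = np.asarray(x, dtype=float)
    za = np.clip(-(x - a) / b, -500, 500)
    zc = np.clip(-(x - a) / c, -500, 500)
    return np.maximum(0.0, np.exp(za) - np.exp(zc)) * d


def ramp_exp(x, a, b, c, d, e):
    x = np.asarray(x, dtype=float)
    z = np.clip(-(x - b) / c, -500, 500)
    return (x - a) * np.exp(z) * d + e


def diffexp_argmax(a: float, b: float, c: float) -> float:
    """Analytic argmax of the difference-of-exponentials bump (b != c)."""
    return a + (b * c / (b - c)) * np.log(b / c)


def ramp_exp_argmax(a: float, c: float) -> float:
    """Analytic argmax of the ramp-times-exponential bump: x* = a + c."""
    return a + c


def _multistart_fit(
    model: Callable,
    x: np.ndarray,
    y: np.ndarray,
    starts: Sequence[Sequence[float]],
    bounds: tuple[Sequence[float], Sequence[float]],
) -> tuple[np.ndarray | None, float]:
    best, best_rss = None, np.inf
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, dtype=float), lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(
                lambda p: model(x, *p) - y, p0, bounds=(lo, hi),
                method="trf", max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        # keep the best residual even when the optimizer stops on a flat
        # plateau without formally declaring success
        if np.isfinite(rss) and rss < best_rss:
            best, best_rss = sol.x, rss
    return best, best_rss


def _grid(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    return np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)


def fit_iv_sigmoid(v, i) -> FitResult:
    """Fit a Boltzmann sigmoid IV curve (I_Na or I_KT).

    Derived quantities: ``half_act`` -- the potential at which the current
    reaches half of its maximal value (= parameter a for the canonical
    sigmoid), and ``i_max`` -- the extremum of the fitted curve over the
    sampled potential range (most negative value for inward currents).
    """
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    ok = np.isfinite(v) & np.isfinite(i)
    v, i = v[ok], i[ok]
    if v.size < 5:
        return FitResult()
    span = float(np.ptp(i))
    if span < 1e-12:
        return FitResult(params={}, derived={"half_act": np.nan, "i_max": 0.0},
                         rss=0.0, converged=False)
    amp = i[np.argmax(np.abs(i))]
    vmid = float(np.median(v))
    starts = [
        (vmid, 8.0, amp, 0.0),
        (vmid - 20.0, 5.0, amp, 0.0),
        (vmid + 20.0, 15.0, amp, 0.0),
        (float(v[np.argmin(np.abs(i - amp / 2))]), 6.0, amp, float(i.min()) if amp > 0 else float(i.max())),
        (vmid, 30.0, 2 * amp, 0.0),
    ]
    amp_bound = 10.0 * max(abs(amp), 1.0)
    best, rss = _multistart_fit(
        sigmoid, v, i, starts,
        ([v.min() - 100.0, 0.5, -amp_bound, -amp_bound],
         [v.max() + 100.0, 200.0, amp_bound, amp_bound]),
    )
    if best is None:
        return FitResult()
    a, b, c, d = best
    grid = _grid(v)
    curve = sigmoid(grid, *best)
    i_max = float(curve[np.argmax(np.abs(curve))])
    return FitResult(
        params=dict(zip("abcd", map(float, best))),
        derived={"half_act": float(a), "i_max": i_max},
        rss=rss, converged=True,
    )


def fit_iv_ks(v, i) -> FitResult:
    """Fit the stable-potassium IV curve with the exponential hinge model.

    ``act`` is the first potential at which the current activates, i.e. the
    smallest v with exp((v-a)/b) > e, which is a + b in closed form.
    ``i_max`` is the maximum of the fit over the sampled range.
    """
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    ok = np.isfinite(v) & np.isfinite(i)
    v, i = v[ok], i[ok]
    if v.size < 5:
        return FitResult()
    if np.ptp(i) < 1e-12:
        return FitResult(derived={"act": np.nan, "i_max": 0.0}, rss=0.0,
                         converged=False)
    imax = float(np.max(i))
    vspan = float(np.ptp(v))
    starts = []
    # informed start from the log-slope of the activated branch (the curve
    # spans orders of magnitude, so blind starts rarely land in the basin)
    pos = i > max(1e-9, 1e-6 * imax)
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(v[pos], np.log(i[pos]), 1)
        if slope > 0:
            b0 = 1.0 / slope
            a0 = float(v[pos][0]) - b0
            c0 = float(np.exp(intercept + a0 / b0))
            starts.append((a0, b0, c0, 0.0))
    starts += [
        (float(np.median(v)) - 10.0, vspan / 6, imax / 20, 0.0),
        (float(v.min()), vspan / 4, imax / 50, 0.0),
        (float(np.median(v)), vspan / 10, imax / 10, 0.0),
        (float(np.median(v)) - 30.0, vspan / 3, imax / 100, 0.0),
        (float(v.min()) - 20.0, vspan / 2, imax / 200, 0.0),
    ]
    cb = 10.0 * max(imax, 1.0)
    best, rss = _multistart_fit(
        ks_hinge, v, i, starts,
        ([v.min() - 200.0, 1.0, 0.0, -cb], [v.max() + 100.0, 500.0, cb, cb]),
    )
    if best is None:
        return FitResult()
    a, b, c, d = best
    grid = _grid(v)
    return FitResult(
        params=dict(zip("abcd", map(float, best))),
        derived={"act": float(a + b), "i_max": float(np.max(ks_hinge(grid, *best)))},
        rss=rss, converged=True,
    )


def _fit_diffexp(x, y, x_scale: float) -> FitResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        return FitResult()
    ymax = float(np.max(y))
    if ymax <= 0:
        return FitResult(derived={"argmax": np.nan, "max": 0.0}, rss=0.0,
                         converged=False)
    xpk = float(x[np.argmax(y)])
    starts = [
        (x.min() - 0.2 * x_scale, 3.0 * x_scale, 0.5 * x_scale, 2 * ymax),
        (xpk - x_scale, 5.0 * x_scale, 0.3 * x_scale, 3 * ymax),
        (x.min(), 2.0 * x_scale, 0.8 * x_scale, 1.5 * ymax),
        (x.min() - x_scale, 10.0 * x_scale, 0.2 * x_scale, 4 * ymax),
        (xpk - 0.5 * x_scale, 1.5 * x_scale, 0.4 * x_scale, 2 * ymax),
    ]
    best, rss = _multistart_fit(
        diffexp, x, y, starts,
        ([x.min() - 10 * x_scale, 1e-3 * x_scale, 1e-3 * x_scale, 0.0],
         [x.max() + 10 * x_scale, 100 * x_scale, 100 * x_scale, 100 * max(ymax, 1.0)]),
    )
    if best is None:
        return FitResult()
    grid = _grid(x)
    curve = diffexp(grid, *best)
    k = int(np.argmax(curve))
    return FitResult(
        params=dict(zip("abcd", map(float, best))),
        derived={"argmax": float(grid[k]), "max": float(curve[k])},
        rss=rss, converged=True,
    )


def fit_spikes_vs_current(currents, counts) -> FitResult:
    """Spike count vs injected current; argmax = 'I best', max = 'N spikes step'."""
    return _fit_diffexp(currents, counts, x_scale=20.0)


def fit_cosine_tuning(periods, counts) -> FitResult:
    """Per-wave spike count vs cosine period; argmax = spiking resonance,
    parameter b = spiking resonance width."""
    return _fit_diffexp(periods, counts, x_scale=10.0)


def _fit_ramp_exp(x, y, x_scale: float) -> FitResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        return FitResult()
    if np.ptp(y) < 1e-12 and abs(float(np.max(y))) < 1e-12:
        return FitResult(derived={"argmax": np.nan, "max": 0.0}, rss=0.0,
                         converged=False)
    xpk = float(x[np.argmax(y)])
    yscale = max(float(np.ptp(y)), abs(float(np.mean(y))), 1e-6)
    starts = [
        (x.min() - 0.5 * x_scale, xpk, xpk - x.min() + 0.5 * x_scale, yscale / x_scale, float(np.min(y))),
        (x.min(), x.min(), x_scale, yscale / x_scale, 0.0),
        (x.min() - x_scale, xpk, 2 * x_scale, 0.5 * yscale / x_scale, float(np.median(y))),
        (x.min() - 0.1 * x_scale, x.max(), 0.5 * x_scale, 2 * yscale / x_scale, float(np.min(y))),
        (x.min() - 2 * x_scale, xpk, 4 * x_scale, 0.1 * yscale / x_scale, 0.0),
    ]
    ybig = 100 * max(abs(float(np.max(y))), 1.0)
    best, rss = _multistart_fit(
        ramp_exp, x, y, starts,
        ([x.min() - 20 * x_scale, x.min() - 20 * x_scale, 1e-3 * x_scale, -ybig, -ybig],
         [x.max() + 20 * x_scale, x.max() + 20 * x_scale, 1e3 * x_scale, ybig, ybig]),
    )
    if best is None:
        return FitResult()
    grid = _grid(x)
    curve = ramp_exp(grid, *best)
    k = int(np.argmax(curve))
    return FitResult(
        params=dict(zip("abcde", map(float, best))),
        derived={"argmax": float(grid[k]), "max": float(curve[k])},
        rss=rss, converged=True,
    )


def fit_wave_train(wave_numbers, counts) -> FitResult:
    """Per-wave spike counts at 100 Hz; argmax = wave buildup, c = wave decay."""
    return _fit_ramp_exp(wave_numbers, counts, x_scale=3.0)


def fit_synaptic_resonance(isis, charges) -> FitResult:
    """Total synaptic charge vs inter-stimulus interval.

    Derived: argmax = synaptic resonance (ms); c = resonance width; max =
    maximal total charge; ppf = max / e (charge under infinitely slow
    stimulation), missing when e <= 0.
    """
    res = _fit_ramp_exp(isis, charges, x_scale=30.0)
    if res.converged:
        e = res.params.get("e", np.nan)
        res.derived["ppf"] = res.derived["max"] / e if e > 0 else np.nan
    return res
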