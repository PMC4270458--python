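"""Regression estimation of the shunting coefficient from voltage traces.

Mirrors an experimental workflow: elicit each input of a pair alone and
both together over a grid of input strengths (here the trials come from the
finite-difference simulator with optional seeded recording noise), smooth
each trace with a centered moving average, measure PSP/SSP amplitudes at
chosen times, scatter the shunting-component amplitude against the product
of the PSP amplitudes, bin and average, and fit a line through the bin
means by ordinary least squares.  The slope is the estimate of k(t) with a
95% confidence interval and R^2; the intercept is retained as a model
check (it should be near zero if the bilinear rule holds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fd import Grid, VoltageTrace, solve_cable, somatic_trace
from .model import CableParams, SynapticInput

__all__ = [
    "NoiseModel",
    "AmplitudeRecord",
    "KEstimate",
    "Trial",
    "TrialSet",
    "moving_average",
    "measure_amplitudes",
    "bin_and_fit",
    "k_timecourse",
    "generate_synthetic_trials",
]

#: Default smoothing lag [ms] for the centered moving average.
DEFAULT_LAG_MS = 2.0
#: k(t) is estimated where the reference PSP exceeds this fraction of its
#: peak, avoiding the small-denominator region.
DEFAULT_TIMECOURSE_FRACTION = 0.2


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian recording noise: sd [mV] at the trace sampling."""

    sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass(frozen=True)
class AmplitudeRecord:
    """Amplitudes of one trial's PSPs and SSP at one measurement time.

    By construction amp_sc = amp_ssp - amp_psp1 - amp_psp2 at the shared
    time.
    """

    trial_id: str
    amp_psp1: float
    amp_psp2: float
    amp_ssp: float
    amp_sc: float
    time: float
    tag: str = "offset"     # 'peak' when the time is the PSP1 peak


@dataclass(frozen=True)
class KEstimate:
    """Fitted slope k [1/mV] with 95% CI, R^2 and fit bookkeeping."""

    slope: float
    ci95: tuple[float, float]
    r2: float
    intercept: float
    n_bins: int
    n_points: int
    time: float | None = None

    def __post_init__(self) -> None:
        if not self.ci95[0] <= self.slope <= self.ci95[1]:
            raise ValueError("confidence interval must contain the slope")


@dataclass
class Trial:
    """One strength combination: each input alone and both together."""

    trial_id: str
    f_a: float
    f_b: float
    psp1: VoltageTrace
    psp2: VoltageTrace
    ssp: VoltageTrace

    def sc(self) -> VoltageTrace:
        return self.ssp - self.psp1 - self.psp2

    def smoothed(self, lag: float = DEFAULT_LAG_MS) -> "Trial":
        return Trial(
            self.trial_id, self.f_a, self.f_b,
            moving_average(self.psp1, lag),
            moving_average(self.psp2, lag),
            moving_average(self.ssp, lag),
        )


@dataclass
class TrialSet:
    trials: list[Trial] = field(default_factory=list)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def times(self) -> np.ndarray:
        return self.trials[0].psp1.times

    def smoothed(self, lag: float = DEFAULT_LAG_MS) -> "TrialSet":
        return TrialSet([t.smoothed(lag) for t in self.trials])


def moving_average(trace: VoltageTrace, lag: float) -> VoltageTrace:
    """Centered moving average with time lag [ms]; edge windows shrink.

    Leaves constants exact and, in the interior, linear ramps exact (the
    centered window is symmetric); reduces white-noise variance roughly by
    the window length.
    """
    dt = trace.dt
    if lag < dt:
        raise ValueError("lag must be at least the sampling interval")
    n_half = int(round(lag / dt / 2))
    window = 2 * n_half + 1
    smoothed = (
        pd.Series(trace.values)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return VoltageTrace(trace.times, smoothed)


def measure_amplitudes(
    psp1: VoltageTrace,
    psp2: VoltageTrace,
    ssp: VoltageTrace,
    times: list,
    trial_id: str = "",
) -> list[AmplitudeRecord]:
    """Amplitude records at the requested times.

    Entries of ``times`` are either floats [ms] or the token 'peak', which
    resolves to the argmax of |psp1| (earliest index on exact ties).
    """
    psp1._check_compatible(psp2)
    psp1._check_compatible(ssp)
    if len(psp1.times) == 0:
        raise ValueError("empty traces")
    records = []
    for t in times:
        if isinstance(t, str):
            if t != "peak":
                raise ValueError(f"unknown time token {t!r}")
            i = int(np.argmax(np.abs(psp1.values)))
            tag = "peak"
        else:
            i = int(np.argmin(np.abs(psp1.times - t)))
            tag = "offset"
        a1 = float(psp1.values[i])
        a2 = float(psp2.values[i])
        a12 = float(ssp.values[i])
        records.append(
            AmplitudeRecord(
                trial_id=trial_id,
                amp_psp1=a1, amp_psp2=a2, amp_ssp=a12,
                amp_sc=a12 - a1 - a2,
                time=float(psp1.times[i]), tag=tag,
            )
        )
    return records


def bin_and_fit(
    records: list[AmplitudeRecord],
    n_bins: int = 10,
    min_per_bin: int = 8,
) -> KEstimate:
    """Bin SC amplitude against the PSP-amplitude product and fit a line.

    The product range is split into ``n_bins`` equal-width bins; empty bins
    are dropped and points within each bin averaged before an ordinary
    least-squares fit (with intercept) through the bin means.  If the
    records are too few for every nonempty bin to hold ``min_per_bin``
    points, the fit falls back to the raw points (n_bins reported as 0).
    The fit is insensitive to the bin count over a broad range.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to fit")
    x = np.array([r.amp_psp1 * r.amp_psp2 for r in records])
    y = np.array([r.amp_sc for r in records])

    used_bins = 0
    if len(records) >= n_bins * min_per_bin and np.ptp(x) > 0:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
        xm, ym = [], []
        for b in range(n_bins):
            m = idx == b
            if m.sum() == 0:
                continue
            xm.append(x[m].mean())
            ym.append(y[m].mean())
        if len(xm) >= 2 and min(
            (idx == b).sum() for b in range(n_bins) if (idx == b).any()
        ) >= min_per_bin:
            x_fit, y_fit = np.array(xm), np.array(ym)
            used_bins = len(xm)
        else:
            x_fit, y_fit = x, y
    else:
        x_fit, y_fit = x, y

    model = sm.OLS(y_fit, sm.add_constant(x_fit)).fit()
    ci = model.conf_int(alpha=0.05)
    return KEstimate(
        slope=float(model.params[1]),
        ci95=(float(ci[1][0]), float(ci[1][1])),
        r2=float(model.rsquared),
        intercept=float(model.params[0]),
        n_bins=used_bins,
        n_points=len(records),
        time=records[0].time if len({r.time for r in records}) == 1 else None,
    )


def k_timecourse(
    trials: TrialSet,
    window: tuple[float, float] | None = None,
    rel_floor: float = DEFAULT_TIMECOURSE_FRACTION,
    stride: int = 1,
    n_bins: int = 10,
    min_per_bin: int = 8,
) -> list[KEstimate]:
    """Regression estimate of k at each time sample inside the window.

    The window defaults to times where the strongest trial's PSP1 exceeds
    ``rel_floor`` of its peak.  R^2 near 1 throughout the window indicates
    the bilinear rule holds at every time, not only at the PSP peak; the CI
    widens toward the window edges as the signal shrinks.
    """
    times = trials.times
    ref = max(trials, key=lambda tr: np.max(np.abs(tr.psp1.values))).psp1
    if window is None:
        mask = np.abs(ref.values) >= rel_floor * np.max(np.abs(ref.values))
    else:
        mask = (times >= window[0]) & (times <= window[1])
        if not mask.any():
            raise ValueError("window outside the simulated interval")
    out = []
    for i in np.flatnonzero(mask)[::stride]:
        t = float(times[i])
        records = [
            measure_amplitudes(tr.psp1, tr.psp2, tr.ssp, [t], tr.trial_id)[0]
            for tr in trials
        ]
        est = bin_and_fit(records, n_bins=n_bins, min_per_bin=min_per_bin)
        out.append(replace(est, time=t))
    return out


def generate_synthetic_trials(
    params: CableParams,
    pair: tuple[SynapticInput, SynapticInput],
    strengths_a: list[float],
    strengths_b: list[float],
    noise: NoiseModel,
    grid: Grid,
) -> TrialSet:
    """FD-simulated trials over a strength grid, emulating recordings.

    For each strength combination the set holds PSP1 alone, PSP2 alone and
    the SSP with both inputs, each with independent seeded Gaussian noise
    added after simulation; zero noise reproduces the FD output exactly and
    a fixed seed reproduces the trials bit for bit.
    """
    inp_a, inp_b = pair
    rng = np.random.default_rng(noise.seed)

    def noisy(trace: VoltageTrace) -> VoltageTrace:
        if noise.sd == 0:
            return trace
        return VoltageTrace(
            trace.times, trace.values + rng.normal(0.0, noise.sd, len(trace.values))
        )

    solo_a = {
        fa: somatic_trace(solve_cable(params, [inp_a.with_strength(fa)], grid))
        for fa in strengths_a
    }
    solo_b = {
        fb: somatic_trace(solve_cable(params, [inp_b.with_strength(fb)], grid))
        for fb in strengths_b
    }
    trials = []
    for fa in strengths_a:
        for fb in strengths_b:
            both = somatic_trace(
                solve_cable(
                    params,
                    [inp_a.with_strength(fa), inp_b.with_strength(fb)],
                    grid,
                )
            )
            trials.append(
                Trial(
                    trial_id=f"fa={fa:.6g},fb={fb:.6g}",
                    f_a=fa, f_b=fb,
                    psp1=noisy(solo_a[fa]),
                    psp2=noisy(solo_b[fb]),
                    ssp=noisy(both),
                )
            )
    return TrialSet(trials)
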