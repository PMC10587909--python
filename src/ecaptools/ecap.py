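"""ECAP epoching, averaging, conduction-velocity windowing and quantification.

The evoked response to each stimulation pulse is extracted as a pulse-aligned
epoch; epochs are combined by point-by-point median (robust to the occasional
artifact-laden sweep); the averaged trace is split into fiber-class time
windows computed from electrode distance and published conduction-velocity
ranges (Abeta 30-70 m/s, B 3-15 m/s); a single-exponential stimulation-artifact
decay can be fitted on ECAP-free segments and subtracted; and magnitude is the
RMS over the (duration-equalized) window.  Authenticity of a putative ECAP is
checked through its propagation delay across spatially separated electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .types import ElectrodeSpec, StimulationTrain, TimeSeriesRecording

#: Published conduction-velocity ranges (m/s) per fiber class.
FIBER_VELOCITY_RANGES = {"Abeta": (30.0, 70.0), "B": (3.0, 15.0)}

#: Maximum relaxation of a velocity bound when the computed window
#: truncates the ECAP.
MAX_VELOCITY_TOLERANCE = 0.20

DEFAULT_FIT_WINDOWS = ((2.2, 2.4), (5.8, 6.0))


@dataclass
class EpochSet:
    """Pulse-aligned voltage segments (pulse x time, uV); time base in ms
    post-stimulus starting at 0."""

    epochs: np.ndarray
    time_base_ms: np.ndarray
    stim_amplitude_ma: float
    channel: Optional[ElectrodeSpec] = None

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.shape[0])


@dataclass
class ECAPTrace:
    """Median-averaged evoked trace on a post-stimulus time base."""

    voltage_uv: np.ndarray
    time_base_ms: np.ndarray
    n_averaged: int
    stim_amplitude_ma: float = 0.0
    channel: Optional[ElectrodeSpec] = None
    detrended: bool = False

    def window_slice(self, t_start_ms: float, t_end_ms: float) -> slice:
        i0 = int(np.searchsorted(self.time_base_ms, t_start_ms, side="left"))
        i1 = int(np.searchsorted(self.time_base_ms, t_end_ms, side="left"))
        return slice(i0, i1)


@dataclass
class FiberWindow:
    """Arrival-time window for one fiber class on one channel."""

    fiber: str
    velocity_range: tuple
    window_ms: tuple
    distance_m: float
    tolerance_applied: float = 0.0
    flagged: bool = False

    @property
    def duration_ms(self) -> float:
        return self.window_ms[1] - self.window_ms[0]


@dataclass
class ExponentialFit:
    """Least-squares fit of y = A exp(-b (x + c)) on artifact-only segments."""

    A: float
    b: float
    c: float
    fit_windows: tuple = DEFAULT_FIT_WINDOWS
    residual_rms_uv: float = np.nan
    converged: bool = False


@dataclass
class EcapMagnitude:
    rms_uv: float
    window: FiberWindow
    detrended: bool = False


def epoch_align(
    rec: TimeSeriesRecording,
    train: Optional[StimulationTrain] = None,
    epoch_length_ms: float = 10.0,
) -> list:
    """Slice each channel into pulse-aligned epochs.

    Returns one :class:`EpochSet` per channel.  A train whose pulses (plus
    the epoch length) extend past the end of the recording is rejected with
    the offending pulse indices; an empty train yields empty epoch sets.
    """
    train = train if train is not None else rec.events
    if train is None:
        raise ValueError("no stimulation train available for epoching")
    fs = rec.sampling_rate
    n_t = int(round(epoch_length_ms * 1e-3 * fs))
    time_base = np.arange(n_t) / fs * 1000.0
    starts = np.round(train.onsets_s * fs).astype(int)
    bad = np.nonzero(starts + n_t > rec.n_samples)[0]
    if bad.size:
        raise ValueError(
            f"pulses {bad.tolist()} extend beyond the recording "
            f"({rec.n_samples} samples)"
        )
    out = []
    for i, ch in enumerate(rec.channels):
        if starts.size:
            epochs = np.stack([rec.samples[i, s : s + n_t] for s in starts])
        else:
            epochs = np.empty((0, n_t))
        out.append(EpochSet(epochs, time_base, train.amplitude_ma, ch))
    return out


def median_average(epochs: EpochSet) -> ECAPTrace:
    """Point-by-point median across epochs.

    The median of n Gaussian-noise sweeps has RMS ~ sigma * sqrt(pi / (2 n))
    — slightly less efficient than the mean but robust to outlier sweeps.
    """
    if epochs.n_epochs < 1:
        raise ValueError("cannot average an empty epoch set")
    return ECAPTrace(
        voltage_uv=np.median(epochs.epochs, axis=0),
        time_base_ms=epochs.time_base_ms.copy(),
        n_averaged=epochs.n_epochs,
        stim_amplitude_ma=epochs.stim_amplitude_ma,
        channel=epochs.channel,
    )


def fiber_window(
    distance_m: float,
    fiber: str = "Abeta",
    velocity_range: Optional[tuple] = None,
) -> FiberWindow:
    """Arrival window (ms) = (distance / v_max, distance / v_min)."""
    if velocity_range is None:
        velocity_range = FIBER_VELOCITY_RANGES[fiber]
    v_min, v_max = velocity_range
    if distance_m <= 0 or v_min <= 0 or v_min >= v_max:
        raise ValueError("require distance > 0 and 0 < v_min < v_max")
    window = (distance_m / v_max * 1000.0, distance_m / v_min * 1000.0)
    return FiberWindow(fiber, (v_min, v_max), window, distance_m)


def estimate_noise_rms(trace: ECAPTrace, window: FiberWindow) -> float:
    """Noise RMS from a quiescent segment outside the fiber window —
    preferring samples after the window (late tail), else before it."""
    sl = trace.window_slice(*window.window_ms)
    tail = trace.voltage_uv[sl.stop :]
    head = trace.voltage_uv[: sl.start]
    seg = tail if tail.size >= 8 else head
    if seg.size == 0:
        seg = np.concatenate([head, tail])
    if seg.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(seg**2)))


def _truncated_edge(
    trace: ECAPTrace, window_ms: tuple, noise_rms: float, n_edge: int = 3
) -> tuple:
    """(start_truncated, end_truncated): is |v| above 3x noise RMS within
    ``n_edge`` samples of either window edge?"""
    sl = trace.window_slice(*window_ms)
    v = np.abs(trace.voltage_uv[sl])
    if v.size == 0:
        return (False, False)
    thr = 3.0 * noise_rms
    start = bool(np.any(v[:n_edge] > thr))
    end = bool(np.any(v[-n_edge:] > thr))
    return (start, end)


def apply_velocity_tolerance(
    window: FiberWindow,
    trace: ECAPTrace,
    noise_rms_uv: Optional[float] = None,
    step: float = 0.01,
) -> FiberWindow:
    """Widen a window edge (by relaxing the corresponding velocity bound in
    1% increments, up to 20%) while the ECAP appears truncated at that edge.

    Truncation is operationalized as |trace| exceeding 3x the quiescent
    noise RMS within 3 samples of the edge.  An untruncated window is
    returned unchanged with ``tolerance_applied == 0``.
    """
    if noise_rms_uv is None:
        noise_rms_uv = estimate_noise_rms(trace, window)
    if noise_rms_uv == 0.0:
        noise_rms_uv = 1e-12  # a perfectly quiet trace has nothing to truncate
    v_min, v_max = window.velocity_range
    d = window.distance_m
    tol_start = tol_end = 0.0
    t_start, t_end = window.window_ms
    while True:
        trunc_start, trunc_end = _truncated_edge(trace, (t_start, t_end), noise_rms_uv)
        moved = False
        if trunc_start and tol_start < MAX_VELOCITY_TOLERANCE - 1e-12:
            tol_start = min(tol_start + step, MAX_VELOCITY_TOLERANCE)
            t_start = d / (v_max * (1.0 + tol_start)) * 1000.0
            moved = True
        if trunc_end and tol_end < MAX_VELOCITY_TOLERANCE - 1e-12:
            tol_end = min(tol_end + step, MAX_VELOCITY_TOLERANCE)
            t_end = d / (v_min * (1.0 - tol_end)) * 1000.0
            moved = True
        t_end = min(t_end, float(trace.time_base_ms[-1]))
        if not moved:
            break
    return FiberWindow(
        fiber=window.fiber,
        velocity_range=window.velocity_range,
        window_ms=(t_start, t_end),
        distance_m=d,
        tolerance_applied=max(tol_start, tol_end),
    )


def _deflection_support(
    trace: ECAPTrace, window: FiberWindow, noise_rms: float
) -> Optional[tuple]:
    """Minimal (t_start, t_end) ms containing all |v| > 3x noise samples in
    the window, or None if the window is signal-free."""
    sl = trace.window_slice(*window.window_ms)
    v = np.abs(trace.voltage_uv[sl])
    idx = np.nonzero(v > 3.0 * noise_rms)[0]
    if idx.size == 0:
        return None
    tb = trace.time_base_ms[sl]
    dt = trace.time_base_ms[1] - trace.time_base_ms[0]
    return (float(tb[idx[0]]), float(tb[idx[-1]]) + dt)


def equalize_windows(
    windows: Sequence[FiberWindow],
    traces: Sequence[ECAPTrace],
    noise_rms_uv: Optional[Sequence[float]] = None,
) -> list:
    """Narrow per-channel fiber windows to a common duration.

    The common duration is the largest of the channels' minimal
    deflection-containing sub-windows, so no channel loses any part of its
    above-noise ECAP; more distant channels no longer carry longer windows
    (and hence more integrated noise) into the RMS comparison.  Signal-free
    channels get the common duration centered inside their velocity window;
    when every channel is signal-free the common duration is the smallest
    input window.  A channel whose velocity window cannot accommodate the
    common duration falls back to its minimal containing window, flagged.
    """
    if len(windows) < 2:
        raise ValueError("window equalization needs at least two channels")
    if noise_rms_uv is None:
        noise_rms_uv = [estimate_noise_rms(t, w) for t, w in zip(traces, windows)]
    supports = [
        _deflection_support(t, w, nr if nr > 0 else 1e-12)
        for t, w, nr in zip(traces, windows, noise_rms_uv)
    ]
    sup_durs = [s[1] - s[0] for s in supports if s is not None]
    if sup_durs:
        common = max(sup_durs)
    else:
        common = min(w.duration_ms for w in windows)

    out = []
    for w, s in zip(windows, supports):
        lo, hi = w.window_ms
        if common > w.duration_ms + 1e-9:
            if s is not None:
                out.append(
                    FiberWindow(w.fiber, w.velocity_range, s, w.distance_m,
                                w.tolerance_applied, flagged=True)
                )
            else:
                out.append(
                    FiberWindow(w.fiber, w.velocity_range, (lo, hi), w.distance_m,
                                w.tolerance_applied, flagged=True)
                )
            continue
        center = (s[0] + s[1]) / 2.0 if s is not None else (lo + hi) / 2.0
        start = center - common / 2.0
        start = min(max(start, lo), hi - common)
        if s is not None:  # keep the deflection fully inside
            start = min(start, s[0])
            start = max(start, s[1] - common)
        out.append(
            FiberWindow(w.fiber, w.velocity_range, (start, start + common),
                        w.distance_m, w.tolerance_applied)
        )
    return out


def detrend_exponential(
    trace: ECAPTrace,
    fit_windows: Sequence[tuple] = DEFAULT_FIT_WINDOWS,
) -> tuple:
    """Fit y = A exp(-b (x + c)) to artifact-decay segments and subtract it.

    The fit uses only samples inside ``fit_windows`` (defaults 2.2-2.4 ms
    and 5.8-6.0 ms, chosen to exclude fiber arrival times so only the
    stimulation-artifact decay — not neural signal — is fitted).  On a
    non-convergent fit the trace is returned unchanged with the fit
    flagged unconverged.
    """
    tb, v = trace.time_base_ms, trace.voltage_uv
    mask = np.zeros(tb.size, dtype=bool)
    for lo, hi in fit_windows:
        if lo < tb[0] - 1e-9 or hi > tb[-1] + (tb[1] - tb[0]) + 1e-9:
            raise ValueError("trace does not cover the exponential fit windows")
        mask |= (tb >= lo) & (tb < hi)
    x, y = tb[mask], v[mask]
    if x.size < 4:
        raise ValueError("too few samples inside the fit windows")

    # log-linear initialization when the decay is positive-going
    if np.all(y > 0):
        slope, intercept = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(intercept)), max(-slope, 1e-6), 0.0)
    else:
        p0 = (float(np.max(np.abs(y)) or 1e-12), 0.5, 0.0)

    def model(p, xx):
        A, b, c = p
        return A * np.exp(np.clip(-b * (xx + c), -700.0, 700.0))

    try:
        res = optimize.least_squares(
            lambda p: model(p, x) - y, p0, max_nfev=2000, method="lm"
        )
        converged = bool(res.success) and np.all(np.isfinite(res.x))
    except Exception:
        res, converged = None, False

    if not converged:
        fit = ExponentialFit(np.nan, np.nan, np.nan, tuple(fit_windows),
                             converged=False)
        return trace, fit

    A, b, c = res.x
    resid = model(res.x, x) - y
    fit = ExponentialFit(
        A=float(A), b=float(b), c=float(c), fit_windows=tuple(fit_windows),
        residual_rms_uv=float(np.sqrt(np.mean(resid**2))), converged=True,
    )
    detrended = ECAPTrace(
        voltage_uv=v - model(res.x, tb),
        time_base_ms=tb.copy(),
        n_averaged=trace.n_averaged,
        stim_amplitude_ma=trace.stim_amplitude_ma,
        channel=trace.channel,
        detrended=True,
    )
    return detrended, fit


def maybe_detrend(
    trace: ECAPTrace,
    fit_windows: Sequence[tuple] = DEFAULT_FIT_WINDOWS,
    noise_rms_uv: Optional[float] = None,
    always: bool = False,
) -> tuple:
    """Detrend only when an artifact decay is actually present.

    A trend is declared when the fitted amplitude inside the first fit
    window exceeds 3x the quiescent noise RMS (artifact contamination was
    the exception, not the rule, in the emulated protocol).  ``always=True``
    forces subtraction regardless.
    """
    detrended, fit = detrend_exponential(trace, fit_windows)
    if always:
        return detrended, fit
    if not fit.converged:
        return trace, fit
    if noise_rms_uv is None:
        # quiescent tail: last 10% of the epoch, after fiber arrivals and
        # long after the artifact decay
        tail = trace.voltage_uv[-max(trace.voltage_uv.size // 10, 8):]
        noise_rms_uv = float(np.sqrt(np.mean(tail**2)))
    level = abs(fit.A * np.exp(-fit.b * (fit_windows[0][0] + fit.c)))
    if level > 3.0 * noise_rms_uv:
        return detrended, fit
    return trace, fit


def ecap_rms(trace: ECAPTrace, window: FiberWindow) -> EcapMagnitude:
    """RMS voltage over the half-open window [t_start, t_end) — the ECAP
    magnitude measure (equals the noise floor when no ECAP is present)."""
    sl = trace.window_slice(*window.window_ms)
    seg = trace.voltage_uv[sl]
    if seg.size == 0:
        raise ValueError("fiber window contains no samples")
    return EcapMagnitude(
        rms_uv=float(np.sqrt(np.mean(seg**2))),
        window=window,
        detrended=trace.detrended,
    )


def estimate_propagation_velocity(
    traces: Sequence[ECAPTrace],
    windows: Optional[Sequence[FiberWindow]] = None,
    fiber_range: Optional[tuple] = None,
    tolerance: float = MAX_VELOCITY_TOLERANCE,
) -> tuple:
    """Conduction velocity from peak-latency shifts across electrodes.

    Latency per channel is the depolarization trough — the minimum voltage —
    inside the fiber window (or the whole trace); using one consistent
    polarity landmark avoids hopping between the two lobes of a biphasic
    deflection.  Velocity is the least-squares slope of distance
    versus latency over channels.  ``authentic`` is True when the velocity
    is finite, positive and — if ``fiber_range`` is given — within the
    class range widened by the velocity tolerance.  Zero latency spread
    (the signature of a common-mode artifact, which arrives everywhere at
    once) gives a non-finite velocity and ``authentic=False``.
    """
    if len(traces) < 2:
        raise ValueError("velocity estimation needs at least two traces")
    distances, latencies = [], []
    for i, tr in enumerate(traces):
        if tr.channel is None:
            raise ValueError("traces must carry channel metadata with distances")
        sl = tr.window_slice(*windows[i].window_ms) if windows else slice(None)
        seg = tr.voltage_uv[sl]
        tb = tr.time_base_ms[sl]
        if seg.size == 0:
            raise ValueError("empty window for velocity estimation")
        latencies.append(tb[int(np.argmin(seg))] * 1e-3)  # s
        distances.append(tr.channel.distance_to_stim_m)
    distances = np.asarray(distances)
    latencies = np.asarray(latencies)
    if len(set(np.round(distances, 9))) < 2:
        raise ValueError("traces must come from distinct distances")
    if np.ptp(latencies) == 0.0:
        return float("inf"), False
    slope = np.polyfit(latencies, distances, 1)[0]
    velocity = float(slope)
    authentic = np.isfinite(velocity) and velocity > 0
    if authentic and fiber_range is not None:
        v_min, v_max = fiber_range
        authentic = v_min * (1 - tolerance) <= velocity <= v_max * (1 + tolerance)
    return velocity, bool(authentic)
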