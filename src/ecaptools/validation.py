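"""Simulation-based calibration experiments.

Each function runs a self-contained experiment on synthetic sessions with
known ground truth and returns the measured quantity: end-to-end EC10
recovery through the full evoked pipeline, spike-detector false-positive
and recall calibration, propagation-velocity authenticity, median-averaging
noise reduction, and type-I error of the cohort comparison.  They are used
by the verification suite and the reproduction script; problem sizes are
arguments so deskside runs can scale down.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, extract_ecp, fit_logistic, normalize_curve
from .ecap import (
    apply_velocity_tolerance,
    ecap_rms,
    epoch_align,
    estimate_propagation_velocity,
    fiber_window,
    median_average,
)
from .filters import FilterSpec, zero_phase_filter
from .presets import cvn_ecap_config
from .simulate import generate_dose_response_session, simulate_recording, spike_template
from .spikes import compute_threshold, detect_spikes
from .stats import cohort_compare
from .types import ElectrodeSpec, StimulationTrain


def ec10_recovery_errors(
    seed: int,
    n_seeds: int = 50,
    n_doses: int = 16,
    train_duration_s: float = 6.0,
) -> np.ndarray:
    """Relative EC10 recovery error, one value per seeded session.

    Each session: ``n_doses`` currents spanning 0-10 mA, a 25 Hz train per
    dose, cuff-like noise (2.53 uVrms), full pipeline (filter -> epoch ->
    median -> velocity window with tolerance -> RMS -> normalize at 5 mA ->
    logistic fit -> EC10) compared against the generating recruitment
    curve's closed-form EC10.
    """
    amps = np.linspace(0.0, 10.0, n_doses)
    errors = []
    for k in range(n_seeds):
        cfg = cvn_ecap_config(seed=int(seed) + k, duration_s=train_duration_s + 0.2)
        cfg.electrodes = cfg.electrodes[:1]  # the cuff channel
        fiber = cfg.fiber_classes[0]
        truth = fiber.recruitment.threshold_ma - np.log(9.0) / fiber.recruitment.slope_per_ma
        recs = generate_dose_response_session(cfg, amps,
                                              train_duration_s=train_duration_s)
        rms = []
        window = None
        for rec in recs:
            filt = zero_phase_filter(rec, FilterSpec())
            tr = median_average(epoch_align(filt, epoch_length_ms=10.0)[0])
            if window is None and rec.events.amplitude_ma == amps.max():
                window = apply_velocity_tolerance(
                    fiber_window(cfg.electrodes[0].distance_to_stim_m, "Abeta"), tr
                )
            rms.append(tr)
        window = window or fiber_window(cfg.electrodes[0].distance_to_stim_m, "Abeta")
        mags = [ecap_rms(tr, window).rms_uv for tr in rms]
        curve = normalize_curve(DoseResponseCurve(amps, mags), 5.0)
        fit = fit_logistic(curve)
        est = extract_ecp(fit, 10.0)
        errors.append(abs(est - truth) / truth)
    return np.asarray(errors)


def spike_false_positive_runs(
    seed: int,
    n_seeds: int = 100,
    duration_s: float = 90.0,
    sampling_rate: float = 25_000.0,
    sigma_uv: float = 2.0,
) -> int:
    """Number of pure-Gaussian-noise sessions with at least one detection.

    Threshold is the mean + 6 SD rule on the 1-6 s baseline; at six sigma
    the expected count is ~2e-3 detections per 90 s session.
    """
    runs_with_fp = 0
    n = int(duration_s * sampling_rate)
    for k in range(n_seeds):
        x = np.random.default_rng(int(seed) + k).normal(0.0, sigma_uv, n)
        thr, _ = compute_threshold(x, sampling_rate)
        if detect_spikes(x, sampling_rate, thr).n_spikes > 0:
            runs_with_fp += 1
    return runs_with_fp


def spike_recall(
    seed: int,
    n_seeds: int = 20,
    n_spikes: int = 40,
    sampling_rate: float = 25_000.0,
    sigma_uv: float = 2.0,
    amplitude_sd: float = 12.0,
) -> float:
    """Recall on spikes injected at ``amplitude_sd`` baseline SDs into
    Gaussian noise (detected within 0.5 ms of an injected time)."""
    found = total = 0
    tpl = spike_template(amplitude_sd * sigma_uv, 1.5, sampling_rate)
    half = tpl.size // 2
    for k in range(n_seeds):
        rng = np.random.default_rng(10_000 + int(seed) + k)
        x = rng.normal(0.0, sigma_uv, int(30.0 * sampling_rate))
        truth = np.sort(rng.uniform(7.0, 29.0, n_spikes))
        truth = truth[np.diff(truth, prepend=0.0) > 0.01]  # well separated
        for t in truth:
            i = int(round(t * sampling_rate))
            x[i - half : i - half + tpl.size] += tpl
        thr, _ = compute_threshold(x, sampling_rate)
        ev = detect_spikes(x, sampling_rate, thr)
        for t in truth:
            total += 1
            if np.any(np.abs(ev.spike_times_s - t) < 0.5e-3):
                found += 1
    return found / total


def velocity_recovery(seed: int = 0) -> float:
    """Estimated conduction velocity (m/s) for a simulated 50 m/s ECAP
    recorded at 0.05 and 0.08 m, through filtering and median averaging."""
    cfg = cvn_ecap_config(seed=int(seed), duration_s=2.2)
    cfg.electrodes = [
        ElectrodeSpec(id="e1", kind="cuff", distance_to_stim_m=0.05,
                      noise_rms_uv=1.0),
        ElectrodeSpec(id="e2", kind="cuff", distance_to_stim_m=0.08,
                      noise_rms_uv=1.0),
    ]
    cfg.stim = StimulationTrain.regular(rate_hz=25.0, train_duration_s=2.0,
                                        amplitude_ma=5.0)
    rec = simulate_recording(cfg)
    filt = zero_phase_filter(rec, FilterSpec())
    traces = [median_average(es) for es in epoch_align(filt, epoch_length_ms=10.0)]
    windows = [
        apply_velocity_tolerance(fiber_window(ch.distance_to_stim_m, "Abeta"), tr)
        for ch, tr in zip(cfg.electrodes, traces)
    ]
    v, authentic = estimate_propagation_velocity(traces, windows,
                                                 fiber_range=(30.0, 70.0))
    if not authentic:
        raise RuntimeError("simulated ECAP failed the authenticity check")
    return v


def common_mode_flagged_nonauthentic() -> bool:
    """A zero-delay artifact injected identically on two channels must fail
    the propagation-delay authenticity check."""
    from .ecap import ECAPTrace

    n = 250
    tb = np.arange(n) / 25_000.0 * 1e3
    artifact = 30.0 * np.exp(-0.8 * tb)
    traces = [
        ECAPTrace(artifact.copy(), tb, n_averaged=1,
                  channel=ElectrodeSpec(id=f"e{i}", distance_to_stim_m=d))
        for i, d in enumerate((0.05, 0.08))
    ]
    v, authentic = estimate_propagation_velocity(traces, fiber_range=(30.0, 70.0))
    return (not authentic) and not np.isfinite(v)


def median_noise_rms(
    seed: int,
    sigma_uv: float = 2.53,
    n_epochs: int = 750,
    n_samples: int = 250,
    reps: int = 20,
) -> float:
    """Mean RMS of the point-wise median of ``n_epochs`` Gaussian sweeps
    (theory: sigma * sqrt(pi / (2 n)))."""
    from .ecap import EpochSet

    rng = np.random.default_rng(int(seed))
    out = []
    for _ in range(reps):
        es = EpochSet(rng.normal(0.0, sigma_uv, (n_epochs, n_samples)),
                      np.arange(n_samples) / 25.0, 0.0)
        tr = median_average(es)
        out.append(float(np.sqrt(np.mean(tr.voltage_uv**2))))
    return float(np.mean(out))


def cohort_type_i_error(
    seed: int,
    n_sims: int = 1000,
    n_subjects: int = 6,
    sigma_log10: float = 0.3,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the one-sided cohort comparison under the null
    (true ratio 1, lognormal between-subject scatter)."""
    hits = 0
    for k in range(n_sims):
        rng = np.random.default_rng(int(seed) + k)
        rows = []
        for s in range(n_subjects):
            ref = 10.0 * 10 ** rng.normal(0.0, 0.1)
            test = ref * 10 ** rng.normal(0.0, sigma_log10)
            rows.append({"subject": s, "kind": "ref", "value": ref})
            rows.append({"subject": s, "kind": "test", "value": test})
        res = cohort_compare(pd.DataFrame(rows), "test", "ref", "less", alpha=alpha)
        hits += res.p_value < alpha
    return hits / n_sims
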