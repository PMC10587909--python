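"""End-to-end pipeline driver.

Runs the evoked path (simulate -> filter -> epoch -> median-average ->
window -> optional detrend -> RMS -> dose-response -> ECp) and/or the
asynchronous path (simulate sensory session -> filter with notch ->
threshold -> detect -> count), writing CSV/JSON results plus a run log
with the config hash and seed so reruns are reproducible.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dose_response import DoseResponseCurve, extract_ecp, fit_logistic, normalize_curve
from .ecap import (
    apply_velocity_tolerance,
    ecap_rms,
    epoch_align,
    equalize_windows,
    estimate_noise_rms,
    fiber_window,
    maybe_detrend,
    median_average,
)
from .filters import FilterSpec, zero_phase_filter
from .io import config_hash
from .presets import cvn_ecap_config, gan_sensory_config
from .simulate import generate_dose_response_session, generate_sensory_session
from .spikes import compute_threshold, count_by_epoch, detect_spikes

DEFAULT_CONFIG = {
    "seed": 0,
    "filter": {
        "highpass_corner_hz": 100.0,
        "highpass_order": 1,
        "lowpass_corner_hz": 3000.0,
    },
    "ecap": {
        "enabled": True,
        "amplitudes_ma": [round(x, 4) for x in np.linspace(0.0, 10.0, 16)],
        "train_duration_s": 6.0,
        "rate_hz": 25.0,
        "epoch_length_ms": 10.0,
        "fiber": "Abeta",
        "notch": False,
        "detrend": "auto",  # auto | always | off
        "normalization_current_ma": 5.0,
    },
    "sensory": {
        "enabled": True,
        "baseline_s": [1.0, 6.0],
        "refractory_ms": 1.0,
    },
    "stats": {"alpha": 0.05},
}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""


def _merge_config(user: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if not user:
        return cfg
    for section, value in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(cfg[section], dict):
            for key, v in value.items():
                if key not in cfg[section]:
                    raise ValueError(f"unknown config key {section}.{key!r}")
                cfg[section][key] = v
        else:
            cfg[section] = value
    return cfg


def run_pipeline(config: dict | None, out_dir, seed: int | None = None) -> Path:
    """Execute the configured stages on simulated sessions; returns out_dir.

    Any stage failure aborts with the stage name while preserving files
    already written.  Identical (config, seed) reruns produce identical
    result files.
    """
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list = []
    if cfg["ecap"]["enabled"] and cfg["ecap"]["notch"]:
        warnings.append(
            "notch enabled on the evoked path: the 60 Hz band-stop is meant "
            "for asynchronous recordings only"
        )

    try:
        if cfg["ecap"]["enabled"]:
            _run_ecap_path(cfg, out_dir, warnings)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        _write_log(cfg, out_dir, warnings + [f"aborted: {exc}"])
        raise PipelineError(f"evoked path failed: {exc}") from exc
    try:
        if cfg["sensory"]["enabled"]:
            _run_sensory_path(cfg, out_dir, warnings)
    except Exception as exc:  # noqa: BLE001
        _write_log(cfg, out_dir, warnings + [f"aborted: {exc}"])
        raise PipelineError(f"asynchronous path failed: {exc}") from exc

    _write_log(cfg, out_dir, warnings)
    return out_dir


def _run_ecap_path(cfg: dict, out_dir: Path, warnings: list) -> None:
    e = cfg["ecap"]
    sim = cvn_ecap_config(seed=cfg["seed"], duration_s=e["train_duration_s"] + 0.1)
    recs = generate_dose_response_session(
        sim, e["amplitudes_ma"], train_duration_s=e["train_duration_s"],
        rate_hz=e["rate_hz"],
    )
    fspec = FilterSpec(notch_enabled=e["notch"], **cfg["filter"])

    # Median-average every dose, per channel.
    traces = {ch.id: [] for ch in sim.electrodes}
    for rec in recs:
        filt = zero_phase_filter(rec, fspec)
        for es in epoch_align(filt, epoch_length_ms=e["epoch_length_ms"]):
            traces[es.channel.id].append(median_average(es))

    # Windows from the highest dose (clearest ECAP), equalized across channels.
    top = int(np.argmax(e["amplitudes_ma"]))
    channels = list(sim.electrodes)
    top_traces = [traces[ch.id][top] for ch in channels]
    windows = [
        apply_velocity_tolerance(
            fiber_window(ch.distance_to_stim_m, e["fiber"]), tr
        )
        for ch, tr in zip(channels, top_traces)
    ]
    windows = equalize_windows(windows, top_traces)
    for w in windows:
        if w.tolerance_applied > 0:
            warnings.append(
                f"velocity tolerance {w.tolerance_applied:.0%} applied on a "
                f"{w.fiber} window"
            )

    rows = []
    for ch, w in zip(channels, windows):
        for amp, tr in zip(e["amplitudes_ma"], traces[ch.id]):
            if e["detrend"] != "off":
                tr, fit = maybe_detrend(tr, always=(e["detrend"] == "always"))
            mag = ecap_rms(tr, w)
            rows.append(
                {
                    "channel": ch.id,
                    "kind": ch.kind,
                    "distance_m": ch.distance_to_stim_m,
                    "fiber": w.fiber,
                    "current_ma": amp,
                    "rms_uv": mag.rms_uv,
                    "t_start_ms": w.window_ms[0],
                    "t_end_ms": w.window_ms[1],
                    "tolerance": w.tolerance_applied,
                    "detrended": mag.detrended,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "dose_response.csv", index=False)

    fit_rows = []
    for ch in channels:
        sub = table[table["channel"] == ch.id]
        curve = DoseResponseCurve(
            sub["current_ma"].to_numpy(), sub["rms_uv"].to_numpy(),
            channel_id=ch.id, fiber=e["fiber"],
        )
        curve = normalize_curve(curve, e["normalization_current_ma"])
        fit = fit_logistic(curve)
        row = {
            "channel": ch.id,
            "kind": ch.kind,
            "fiber": e["fiber"],
            "L": fit.L, "k": fit.k, "x0": fit.x0, "y0": fit.y0,
            "residual_rms": fit.residual_rms,
            "converged": fit.converged,
            "flat": fit.flat,
        }
        if fit.converged:
            row["ec10_ma"] = extract_ecp(fit, 10.0)
            row["ec50_ma"] = extract_ecp(fit, 50.0)
        fit_rows.append(row)
    pd.DataFrame(fit_rows).to_csv(out_dir / "logistic_fits.csv", index=False)


def _run_sensory_path(cfg: dict, out_dir: Path, warnings: list) -> None:
    s = cfg["sensory"]
    sim = gan_sensory_config(seed=cfg["seed"])
    rec = generate_sensory_session(sim)
    fspec = FilterSpec(notch_enabled=True, **cfg["filter"])
    filt = zero_phase_filter(rec, fspec)

    spike_rows, counts = [], {}
    for ch in filt.channels:
        trace = filt.channel(ch.id)
        threshold, degenerate = compute_threshold(
            trace, filt.sampling_rate, tuple(s["baseline_s"])
        )
        if degenerate:
            warnings.append(f"degenerate (zero-variance) baseline on {ch.id}")
        events = detect_spikes(
            trace, filt.sampling_rate, threshold, refractory_ms=s["refractory_ms"]
        )
        events = count_by_epoch(events, rec.annotations["epochs"])
        counts[ch.id] = {
            "threshold_uv": events.threshold_uv,
            "counts": events.per_epoch_counts,
            "outside": events.n_outside_epochs,
        }
        for t, pk in zip(events.spike_times_s, events.peak_uv):
            label = next(
                (lab for lab, a, b in rec.annotations["epochs"] if a <= t < b), ""
            )
            spike_rows.append(
                {"channel": ch.id, "time_s": t, "peak_uv": pk, "epoch": label}
            )
    pd.DataFrame(
        spike_rows, columns=["channel", "time_s", "peak_uv", "epoch"]
    ).to_csv(out_dir / "spikes.csv", index=False)
    (out_dir / "spike_counts.json").write_text(json.dumps(counts, indent=1))


def _write_log(cfg: dict, out_dir: Path, warnings: list) -> None:
    log = {
        "package": f"ecaptools {__version__}",
        "numpy": np.__version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "warnings": warnings,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
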