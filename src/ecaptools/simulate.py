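"""Seeded synthetic nerve-recording generator.

Emulates the statistical structure of cervical-vagus / auricular-nerve
recording sessions: per-pulse epochs containing an exponential-decay
stimulation artifact plus fiber-class ECAPs whose latency is
distance / conduction velocity and whose amplitude follows a sigmoid
recruitment curve versus current; additive noise layers (white
electronics noise, mains, low-frequency drift); periodic motion
artifacts (ventilator, cardiac, tremor bursts); and 90 s sensory
sessions of quiescent / on-target / off-target multi-unit spiking.

Randomness policy: one root seed; every stochastic layer draws from its
own child stream keyed by (layer, channel, trial), so adding or removing
a layer never perturbs the others and the superposition of separately
simulated layers equals the combined simulation bit for bit.
"""

from __future__ import annotations

import copy
from typing import Optional, Sequence

import numpy as np

from .types import (
    ElectrodeSpec,
    FiberClassSpec,
    SimulationConfig,
    StimulationTrain,
    TimeSeriesRecording,
)

_LAYER_KEYS = {
    "white": 1,
    "mains": 2,
    "drift": 3,
    "tremor": 4,
    "sensory": 5,
    "order": 6,
}

_N_DRIFT_TONES = 20


def _rng(seed: int, layer: str, channel: int = 0, trial: int = 0) -> np.random.Generator:
    key = (_LAYER_KEYS[layer], channel, trial)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def recruitment_fraction(current_ma: float, spec: FiberClassSpec) -> float:
    """Ground-truth recruited fraction of a fiber class at a given current.

    Scaled logistic ``sat / (1 + exp(-k (I - I50)))`` — the same sigmoidal
    form the dose-response fits assume — with an exact zero at 0 mA
    (no stimulus recruits nothing).  Monotone nondecreasing in current.
    """
    if current_ma < 0:
        raise ValueError("stimulation current must be nonnegative")
    if current_ma == 0:
        return 0.0
    r = spec.recruitment
    return float(
        r.saturation / (1.0 + np.exp(-r.slope_per_ma * (current_ma - r.threshold_ma)))
    )


def fiber_template(fiber: FiberClassSpec, sampling_rate: float) -> np.ndarray:
    """Biphasic unit-gain template: one negative then one positive lobe,
    peak amplitude ``fiber.peak_uv``, zero mean."""
    n = max(int(round(fiber.duration_ms * 1e-3 * sampling_rate)), 4)
    phase = np.arange(n) / n
    return -fiber.peak_uv * np.sin(2.0 * np.pi * phase)


def spike_template(amplitude_uv: float, duration_ms: float, sampling_rate: float) -> np.ndarray:
    """Triphasic extracellular spike: Ricker wavelet with a dominant positive
    central peak flanked by two negative lobes ('multi-unit hash' shape)."""
    n = max(int(round(duration_ms * 1e-3 * sampling_rate)), 5)
    t = np.arange(n) - (n - 1) / 2.0
    sigma = n / 6.0
    x = (t / sigma) ** 2
    return amplitude_uv * (1.0 - x) * np.exp(-x / 2.0)


def _add_at(trace: np.ndarray, start: int, wave: np.ndarray) -> None:
    """Add ``wave`` into ``trace`` starting at sample ``start``, clipping."""
    n = trace.size
    if start >= n or start + wave.size <= 0:
        return
    a = max(start, 0)
    b = min(start + wave.size, n)
    trace[a:b] += wave[a - start : b - start]


def _check_epoch_overlap(config: SimulationConfig) -> None:
    stim = config.stim
    if stim is None or stim.count == 0:
        return
    interval_ms = 1000.0 / stim.rate_hz
    for ch in config.electrodes:
        for fiber in config.fiber_classes:
            lat_ms = ch.distance_to_stim_m / fiber.velocity_m_s * 1000.0
            if lat_ms + fiber.duration_ms > interval_ms:
                raise ValueError(
                    f"fiber {fiber.name!r} response on channel {ch.id!r} "
                    f"({lat_ms + fiber.duration_ms:.2f} ms) overlaps the next "
                    f"pulse at {stim.rate_hz} Hz ({interval_ms:.2f} ms interval)"
                )
    tail = max(
        (
            ch.distance_to_stim_m / fiber.velocity_m_s + fiber.duration_ms * 1e-3
            for ch in config.electrodes
            for fiber in config.fiber_classes
        ),
        default=0.0,
    )
    if stim.onsets_s[-1] + tail > config.duration_s:
        raise ValueError("last pulse response extends beyond the recording")


def _render_neural(
    config: SimulationConfig,
    ch: ElectrodeSpec,
    n: int,
    distance_m: Optional[float] = None,
) -> np.ndarray:
    """Deterministic neural (ECAP) component of one channel."""
    trace = np.zeros(n)
    stim = config.stim
    if stim is None or stim.count == 0:
        return trace
    d = ch.distance_to_stim_m if distance_m is None else distance_m
    fs = config.sampling_rate
    for fiber in config.fiber_classes:
        frac = recruitment_fraction(stim.amplitude_ma, fiber)
        scale = frac * ch.gain_for(fiber.name)
        if scale == 0.0:
            continue
        wave = fiber_template(fiber, fs) * scale
        latency_s = d / fiber.velocity_m_s
        for onset in stim.onsets_s:
            _add_at(trace, int(round((onset + latency_s) * fs)), wave)
    return trace


def _render_common_mode(config: SimulationConfig, n: int, trial: int) -> np.ndarray:
    """Common-mode artifact layer (unit channel scale): stimulation-artifact
    decay plus ventilator / cardiac / tremor motion artifacts."""
    fs = config.sampling_rate
    trace = np.zeros(n)
    art = config.artifacts

    sa = art.stim_artifact
    if sa is not None and sa.amplitude_uv > 0 and config.stim is not None:
        interval_ms = 1000.0 / config.stim.rate_hz if config.stim.count else 40.0
        sup_ms = min(np.log(max(sa.amplitude_uv, 1e-6) / 1e-3) / sa.decay_per_ms
                     - sa.offset_ms, interval_ms)
        m = max(int(round(sup_ms * 1e-3 * fs)), 1)
        t_ms = np.arange(m) / fs * 1000.0
        decay = sa.amplitude_uv * np.exp(-sa.decay_per_ms * (t_ms + sa.offset_ms))
        for onset in config.stim.onsets_s:
            _add_at(trace, int(round(onset * fs)), decay)

    if art.ventilator_amplitude_uv > 0 and art.ventilator_rate_per_min > 0:
        period = 60.0 / art.ventilator_rate_per_min
        wave = _motion_bump(art.ventilator_amplitude_uv, 0.30, fs)
        for k in range(int(config.duration_s / period) + 1):
            _add_at(trace, int(round(k * period * fs)), wave)

    if art.cardiac_amplitude_uv > 0 and art.cardiac_rate_bpm > 0:
        period = 60.0 / art.cardiac_rate_bpm
        wave = _motion_bump(art.cardiac_amplitude_uv, 0.05, fs)
        for k in range(int(config.duration_s / period) + 1):
            _add_at(trace, int(round(k * period * fs)), wave)

    if art.tremor_amplitude_uv > 0 and art.tremor_rate_per_min > 0:
        rng = _rng(config.seed, "tremor", 0, trial)
        n_bursts = rng.poisson(art.tremor_rate_per_min * config.duration_s / 60.0)
        starts = np.sort(rng.uniform(0, config.duration_s, n_bursts))
        m = int(round(0.2 * fs))
        t = np.arange(m) / fs
        burst = (
            art.tremor_amplitude_uv
            * np.sin(2 * np.pi * 10.0 * t)
            * np.hanning(m)
        )
        for s in starts:
            _add_at(trace, int(round(s * fs)), burst)

    return trace


def _motion_bump(amplitude_uv: float, width_s: float, fs: float) -> np.ndarray:
    """Slow biphasic motion-artifact wavelet (derivative-of-Gaussian)."""
    m = max(int(round(width_s * fs)), 8)
    t = np.arange(m) - (m - 1) / 2.0
    sigma = m / 6.0
    w = -t / sigma * np.exp(-(t**2) / (2 * sigma**2) + 0.5)
    return amplitude_uv * w


def _render_noise(
    config: SimulationConfig, ch: ElectrodeSpec, chan_idx: int, n: int, trial: int
) -> np.ndarray:
    """Channel-specific stochastic noise: white + mains + low-frequency drift.

    The white component's RMS is the quadrature sum of the global
    ``NoiseSpec.white_rms_uv`` and the per-channel ``ElectrodeSpec.noise_rms_uv``.
    """
    fs = config.sampling_rate
    noise = config.noise
    trace = np.zeros(n)

    sigma = float(np.hypot(noise.white_rms_uv, ch.noise_rms_uv))
    if sigma > 0:
        trace += sigma * _rng(config.seed, "white", chan_idx, trial).standard_normal(n)

    if noise.mains_amplitude_uv > 0:
        phase = _rng(config.seed, "mains", chan_idx, trial).uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        trace += noise.mains_amplitude_uv * np.sin(
            2 * np.pi * noise.mains_freq_hz * t + phase
        )

    if noise.drift_rms_uv > 0:
        rng = _rng(config.seed, "drift", chan_idx, trial)
        t = np.arange(n) / fs
        amp = noise.drift_rms_uv * np.sqrt(2.0 / _N_DRIFT_TONES)
        for _ in range(_N_DRIFT_TONES):
            f = rng.uniform(0.1, 9.5)
            ph = rng.uniform(0, 2 * np.pi)
            trace += amp * np.sin(2 * np.pi * f * t + ph)

    return trace


def simulate_recording(
    config: SimulationConfig, trial: int = 0, keep_layers: bool = True
) -> TimeSeriesRecording:
    """Generate one multichannel recording from ``config``.

    Each pulse inserts, on every channel, one ECAP template per fiber class
    at latency distance/velocity, scaled by the recruitment fraction at the
    train amplitude times the channel gain; common-mode artifact and noise
    layers are added on top.  Ground truth (the config itself) is retained
    on the returned recording.  Identical (config, seed, trial) is
    bit-reproducible.
    """
    config.validate()
    _check_epoch_overlap(config)
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))

    n_ch = len(config.electrodes)
    neural = np.zeros((n_ch, n))
    common = np.zeros((n_ch, n))
    noise = np.zeros((n_ch, n))
    common_raw = _render_common_mode(config, n, trial)
    for i, ch in enumerate(config.electrodes):
        neural[i] = _render_neural(config, ch, n)
        common[i] = common_raw * ch.artifact_scale
        noise[i] = _render_noise(config, ch, i, n, trial)

    samples = neural + common + noise
    layers = {"neural": neural, "common_mode": common, "noise": noise}
    return TimeSeriesRecording(
        samples=samples,
        sampling_rate=fs,
        channels=list(config.electrodes),
        events=config.stim,
        ground_truth=config,
        layers=layers if keep_layers else None,
    )


def generate_sensory_session(config: SimulationConfig, trial: int = 0) -> TimeSeriesRecording:
    """Generate a sensory session (canonically 90 s: quiescent / on-target /
    off-target 30 s epochs) with Poisson multi-unit spiking.

    Spike times and jittered amplitudes are shared across channels (the same
    physical units fire); each channel scales them by its kind-specific
    ``spike_gain``, so a microneurography channel sees large spikes while
    cuff/LIFE channels see the same events far below their noise floor.
    Ground-truth spike times per epoch are stored in ``annotations``.
    """
    paradigm = config.artifacts.sensory_paradigm
    if paradigm is None:
        raise ValueError("config.artifacts.sensory_paradigm is required")
    config = copy.deepcopy(config)
    config.duration_s = paradigm.total_duration()
    config.stim = None
    config.validate()

    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    rng = _rng(config.seed, "sensory", 0, trial)

    spike_times, spike_amps, by_epoch = [], [], {}
    for label, start, end in paradigm.boundaries():
        rate = next(r for lab, d, r in paradigm.epochs if lab == label)
        count = rng.poisson(rate * (end - start))
        times = np.sort(rng.uniform(start, end, count))
        amps = paradigm.spike_amplitude_uv * rng.uniform(0.7, 1.3, count)
        by_epoch[label] = times
        spike_times.append(times)
        spike_amps.append(amps)
    spike_times = np.concatenate(spike_times) if spike_times else np.empty(0)
    spike_amps = np.concatenate(spike_amps) if spike_amps else np.empty(0)

    n_ch = len(config.electrodes)
    neural = np.zeros((n_ch, n))
    common = np.zeros((n_ch, n))
    noise = np.zeros((n_ch, n))
    common_raw = _render_common_mode(config, n, trial)
    base = spike_template(1.0, paradigm.spike_duration_ms, fs)
    half = base.size // 2
    for i, ch in enumerate(config.electrodes):
        for t, a in zip(spike_times, spike_amps):
            _add_at(neural[i], int(round(t * fs)) - half, base * a * ch.spike_gain)
        common[i] = common_raw * ch.artifact_scale
        noise[i] = _render_noise(config, ch, i, n, trial)

    rec = TimeSeriesRecording(
        samples=neural + common + noise,
        sampling_rate=fs,
        channels=list(config.electrodes),
        ground_truth=config,
        layers={"neural": neural, "common_mode": common, "noise": noise},
    )
    rec.annotations["spike_times"] = by_epoch
    rec.annotations["epochs"] = paradigm.boundaries()
    return rec


def generate_dose_response_session(
    config: SimulationConfig,
    amplitudes_ma: Sequence[float],
    train_duration_s: Optional[float] = None,
    rate_hz: float = 25.0,
    pulse_width_us: float = 200.0,
) -> list:
    """One stimulation-train recording per dose amplitude.

    All recordings share electrodes and noise parameters; noise streams are
    keyed by the dose index so the session is reproducible regardless of
    presentation order.  The seeded shuffled presentation order (doses were
    presented randomized in the emulated protocol) is stored in each
    recording's annotations; the returned list is in input-amplitude order.
    """
    amplitudes = list(amplitudes_ma)
    if len(amplitudes) < 2:
        raise ValueError("at least two dose amplitudes are required")
    if train_duration_s is None:
        train_duration_s = config.duration_s - 2.0 / rate_hz
    order = _rng(config.seed, "order").permutation(len(amplitudes))

    recordings = []
    for i, amp in enumerate(amplitudes):
        cfg = copy.deepcopy(config)
        cfg.stim = StimulationTrain.regular(
            rate_hz=rate_hz,
            train_duration_s=train_duration_s,
            amplitude_ma=amp,
            pulse_width_us=pulse_width_us,
        )
        rec = simulate_recording(cfg, trial=i)
        rec.annotations["dose_index"] = i
        rec.annotations["presentation_order"] = order.tolist()
        recordings.append(rec)
    return recordings


def apply_reference(rec: TimeSeriesRecording, channel_id: str) -> np.ndarray:
    """Model a referencing strategy for one channel of a simulated recording.

    * ``local_tissue`` — recording contact against a far tissue reference:
      neural signal plus the common-mode artifact layer at full amplitude.
    * ``bipolar`` — difference of the neural component at the contact and at
      a second on-nerve contact ``contact_spacing_m`` further from the
      stimulation site; the common-mode layer cancels exactly.
    * ``tripolar`` — center contact minus the mean of the two flanking
      contacts; common-mode again cancels.

    On-nerve modes keep the channel's own (uncorrelated) noise layer.
    Requires simulator ground truth to re-render the neural signal at the
    displaced reference contacts.
    """
    idx = rec.channel_index(channel_id)
    ch = rec.channels[idx]
    if ch.reference == "local_tissue":
        return rec.samples[idx].copy()
    if rec.ground_truth is None or rec.layers is None:
        raise ValueError("on-nerve reference modelling requires simulator ground truth")
    if ch.reference not in ("bipolar", "tripolar"):
        raise ValueError(f"unknown reference mode {ch.reference!r}")

    cfg = rec.ground_truth
    n = rec.n_samples
    d = ch.distance_to_stim_m
    spacing = ch.contact_spacing_m
    center = _render_neural(cfg, ch, n, distance_m=d)
    noise = rec.layers["noise"][idx]
    if ch.reference == "bipolar":
        far = _render_neural(cfg, ch, n, distance_m=d + spacing)
        return center - far + noise
    near = _render_neural(cfg, ch, n, distance_m=max(d - spacing, 1e-6))
    far = _render_neural(cfg, ch, n, distance_m=d + spacing)
    return center - 0.5 * (near + far) + noise
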