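"""Domain containers shared across the package.

Conventions: voltages are microvolts (uV) in memory, time is seconds from
recording start, epoch/window time bases are milliseconds post-stimulus.
Disk formats store volts (see :mod:`ecaptools.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

ELECTRODE_KINDS = ("cuff", "microneurography", "life")
REFERENCE_MODES = ("local_tissue", "bipolar", "tripolar")

#: Default spike-amplitude scaling per electrode kind for sensory sessions.
#: A penetrating microelectrode sits next to the firing axons; cuff and LIFE
#: macroelectrodes see multi-unit activity attenuated far below their noise.
DEFAULT_SPIKE_GAIN = {"microneurography": 1.0, "life": 0.08, "cuff": 0.04}


@dataclass
class RecruitmentSpec:
    """Sigmoid recruitment of a fiber class versus stimulation current.

    ``threshold_ma`` is the midpoint (50% of saturation), ``slope_per_ma``
    the logistic growth rate, ``saturation`` the asymptotic recruited
    fraction in [0, 1].
    """

    threshold_ma: float = 1.0
    slope_per_ma: float = 4.0
    saturation: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.saturation <= 1.0):
            raise ValueError("recruitment saturation must be in [0, 1]")
        if self.slope_per_ma <= 0:
            raise ValueError("recruitment slope must be positive")


@dataclass
class FiberClassSpec:
    """A conduction-velocity fiber class and its ECAP template parameters.

    The template is a single biphasic deflection (negative lobe leading,
    as for a passing depolarization dipole) with peak amplitude
    ``peak_uv`` at unit channel gain and total duration ``duration_ms``.
    When ``duration_ms`` is None it defaults to ``20 / velocity`` ms, so
    faster fibers produce shorter deflections (dipole-length analogy).
    """

    name: str
    velocity_m_s: float
    peak_uv: float = 20.0
    duration_ms: Optional[float] = None
    recruitment: RecruitmentSpec = field(default_factory=RecruitmentSpec)

    def __post_init__(self) -> None:
        if self.velocity_m_s <= 0:
            raise ValueError("fiber conduction velocity must be positive")
        if self.duration_ms is None:
            self.duration_ms = 20.0 / self.velocity_m_s
        if self.duration_ms <= 0:
            raise ValueError("template duration must be positive")
        self.recruitment.validate()


@dataclass
class ElectrodeSpec:
    """Recording contact metadata.

    ``gain_per_fiber_class`` scales inserted ECAP templates, either one
    float for every class or a mapping ``{fiber name: gain}``.  ``reference``
    selects the referencing strategy modelled by
    :func:`ecaptools.simulate.apply_reference`.
    """

    id: str
    kind: str = "cuff"
    distance_to_stim_m: float = 0.05
    gain_per_fiber_class: object = 1.0
    noise_rms_uv: float = 0.0
    reference: str = "local_tissue"
    contact_spacing_m: Optional[float] = None
    artifact_scale: float = 1.0
    spike_gain: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ELECTRODE_KINDS:
            raise ValueError(f"unknown electrode kind {self.kind!r}")
        if self.reference not in REFERENCE_MODES:
            raise ValueError(f"unknown reference mode {self.reference!r}")
        if self.distance_to_stim_m <= 0:
            raise ValueError("distance_to_stim_m must be positive")
        if self.noise_rms_uv < 0:
            raise ValueError("noise_rms_uv must be nonnegative")
        if self.reference != "local_tissue" and not self.contact_spacing_m:
            raise ValueError("on-nerve references require contact_spacing_m")
        if self.spike_gain is None:
            self.spike_gain = DEFAULT_SPIKE_GAIN[self.kind]

    def gain_for(self, fiber: str) -> float:
        if isinstance(self.gain_per_fiber_class, dict):
            return float(self.gain_per_fiber_class.get(fiber, 1.0))
        return float(self.gain_per_fiber_class)


@dataclass
class NoiseSpec:
    """Additive noise layers: white electronics noise, 60 Hz mains, slow drift."""

    white_rms_uv: float = 0.0
    mains_amplitude_uv: float = 0.0
    mains_freq_hz: float = 60.0
    drift_rms_uv: float = 0.0

    def validate(self) -> None:
        for v in (self.white_rms_uv, self.mains_amplitude_uv, self.drift_rms_uv):
            if v < 0:
                raise ValueError("noise amplitudes must be nonnegative")


@dataclass
class StimArtifactSpec:
    """Per-pulse exponential stimulation-artifact decay A*exp(-b*(t+c))."""

    amplitude_uv: float = 0.0   # A
    decay_per_ms: float = 0.8   # b
    offset_ms: float = 0.0      # c


@dataclass
class SensoryParadigm:
    """Ordered epoch schedule for a sensory session.

    ``epochs`` is a sequence of (label, duration_s, spike_rate_hz); the
    canonical paradigm is 30 s quiescent / 30 s on-target / 30 s off-target.
    """

    epochs: Sequence[tuple] = (
        ("quiescent", 30.0, 0.5),
        ("on_target", 30.0, 20.0),
        ("off_target", 30.0, 1.0),
    )
    spike_amplitude_uv: float = 40.0
    spike_duration_ms: float = 1.5

    def total_duration(self) -> float:
        return float(sum(d for _, d, _ in self.epochs))

    def boundaries(self) -> list:
        """Return [(label, start_s, end_s)] with half-open intervals."""
        out, t = [], 0.0
        for label, dur, _ in self.epochs:
            out.append((label, t, t + dur))
            t += dur
        return out


@dataclass
class ArtifactSpec:
    """Artifact layers: stimulation decay plus periodic motion artifacts."""

    stim_artifact: Optional[StimArtifactSpec] = None
    ventilator_rate_per_min: float = 15.0
    ventilator_amplitude_uv: float = 0.0
    cardiac_rate_bpm: float = 90.0
    cardiac_amplitude_uv: float = 0.0
    tremor_rate_per_min: float = 0.0
    tremor_amplitude_uv: float = 0.0
    sensory_paradigm: Optional[SensoryParadigm] = None

    def validate(self) -> None:
        for v in (
            self.ventilator_rate_per_min,
            self.ventilator_amplitude_uv,
            self.cardiac_rate_bpm,
            self.cardiac_amplitude_uv,
            self.tremor_rate_per_min,
            self.tremor_amplitude_uv,
        ):
            if v < 0:
                raise ValueError("artifact rates/amplitudes must be nonnegative")


@dataclass
class StimulationTrain:
    """Pulse onset times with shared amplitude, width and rate."""

    onsets_s: np.ndarray
    amplitude_ma: float
    pulse_width_us: float = 200.0
    rate_hz: float = 25.0
    train_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.size > 1 and not np.all(np.diff(self.onsets_s) > 0):
            raise ValueError("stimulation onsets must be strictly increasing")
        if self.train_duration_s is None and self.onsets_s.size:
            self.train_duration_s = self.onsets_s.size / self.rate_hz

    @classmethod
    def regular(
        cls,
        rate_hz: float = 25.0,
        train_duration_s: float = 30.0,
        amplitude_ma: float = 1.5,
        pulse_width_us: float = 200.0,
        start_s: float = 0.0,
    ) -> "StimulationTrain":
        """Regular train; pulse count = round(rate * duration) (e.g. 750 at
        25 Hz for 30 s)."""
        count = int(round(rate_hz * train_duration_s))
        onsets = start_s + np.arange(count) / rate_hz
        return cls(onsets, amplitude_ma, pulse_width_us, rate_hz, train_duration_s)

    @property
    def count(self) -> int:
        return int(self.onsets_s.size)


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic recording."""

    sampling_rate: float = 25_000.0
    duration_s: float = 30.0
    seed: int = 0
    fiber_classes: Sequence[FiberClassSpec] = field(default_factory=list)
    electrodes: Sequence[ElectrodeSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    stim: Optional[StimulationTrain] = None

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        self.noise.validate()
        self.artifacts.validate()


@dataclass
class TimeSeriesRecording:
    """Multichannel voltage trace plus metadata.

    ``samples`` is (n_channels, n_samples) in uV.  ``layers`` optionally
    keeps the per-channel additive components ("neural", "common_mode",
    "noise") so referencing strategies and superposition checks can be
    computed exactly.  ``annotations`` carries simulator ground truth such
    as inserted spike times or the shuffled dose order.
    """

    samples: np.ndarray
    sampling_rate: float
    channels: Sequence[ElectrodeSpec]
    events: Optional[StimulationTrain] = None
    ground_truth: Optional[SimulationConfig] = None
    layers: Optional[dict] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel metadata count must match sample rows")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, channel_id: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.id == channel_id:
                return i
        raise KeyError(f"no channel with id {channel_id!r}")

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_index(channel_id)]
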