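"""Preset simulation configurations emulating the study conditions.

These are the default scenarios the examples, pipeline demo and
verification suites run on: a cervical-vagus ECAP session (three
electrode types at staggered distances downstream of a bipolar
stimulation cuff, 25 kHz sampling, filtered cuff noise floor ~2.5 uVrms)
and a 90 s auricular sensory session (quiescent / on-target / off-target
30 s epochs).
"""

from __future__ import annotations

from .types import (
    ArtifactSpec,
    ElectrodeSpec,
    FiberClassSpec,
    NoiseSpec,
    RecruitmentSpec,
    SensoryParadigm,
    SimulationConfig,
    StimArtifactSpec,
)

#: Relative ECAP gain per electrode kind.  The cuff sums potentials from
#: every fiber inside it and records the largest ECAP; the penetrating
#: microelectrode weights nearby fibers only.  Ratios are plausible gain
#: knobs, not derived quantities.
ECAP_GAIN = {"cuff": 1.0, "life": 0.34, "microneurography": 0.21}

#: Filtered time-series noise floor per kind, uVrms.
NOISE_RMS = {"cuff": 2.53, "life": 2.53, "microneurography": 3.51}


def abeta_fiber(
    velocity_m_s: float = 50.0,
    peak_uv: float = 20.0,
    threshold_ma: float = 1.0,
    slope_per_ma: float = 4.0,
) -> FiberClassSpec:
    """A fast myelinated (Abeta) fiber class with sigmoid recruitment."""
    return FiberClassSpec(
        name="Abeta",
        velocity_m_s=velocity_m_s,
        peak_uv=peak_uv,
        recruitment=RecruitmentSpec(threshold_ma, slope_per_ma, 1.0),
    )


def b_fiber(velocity_m_s: float = 10.0, peak_uv: float = 4.0) -> FiberClassSpec:
    """A slow myelinated (B) fiber class: smaller, later, higher threshold."""
    return FiberClassSpec(
        name="B",
        velocity_m_s=velocity_m_s,
        peak_uv=peak_uv,
        recruitment=RecruitmentSpec(threshold_ma=3.0, slope_per_ma=2.0),
    )


def cvn_electrodes(distances_m=(0.05, 0.08, 0.11)) -> list:
    """One contact each of cuff / LIFE / microneurography at staggered
    distances (>4 cm from the stimulation cuff)."""
    kinds = ("cuff", "life", "microneurography")
    out = []
    for kind, d in zip(kinds, distances_m):
        out.append(
            ElectrodeSpec(
                id=f"{kind}_1",
                kind=kind,
                distance_to_stim_m=d,
                gain_per_fiber_class=ECAP_GAIN[kind],
                noise_rms_uv=NOISE_RMS[kind],
            )
        )
    return out


def cvn_ecap_config(
    seed: int = 0,
    duration_s: float = 6.0,
    electrodes=None,
    with_artifact: bool = False,
) -> SimulationConfig:
    """Cervical-vagus ECAP session scaffold (attach a train or pass to
    generate_dose_response_session)."""
    artifacts = ArtifactSpec(
        stim_artifact=StimArtifactSpec(amplitude_uv=50.0, decay_per_ms=0.8)
        if with_artifact
        else None
    )
    return SimulationConfig(
        sampling_rate=25_000.0,
        duration_s=duration_s,
        seed=seed,
        fiber_classes=[abeta_fiber()],
        electrodes=electrodes if electrodes is not None else cvn_electrodes(),
        noise=NoiseSpec(),
        artifacts=artifacts,
    )


def gan_sensory_config(seed: int = 0, with_ventilator: bool = True) -> SimulationConfig:
    """90 s auricular sensory session: quiescent / on-target / off-target."""
    electrodes = [
        ElectrodeSpec(id="micro_1", kind="microneurography",
                      distance_to_stim_m=0.03, noise_rms_uv=2.5),
        ElectrodeSpec(id="cuff_1", kind="cuff",
                      distance_to_stim_m=0.03, noise_rms_uv=2.5),
        ElectrodeSpec(id="life_1", kind="life",
                      distance_to_stim_m=0.03, noise_rms_uv=2.5),
    ]
    artifacts = ArtifactSpec(
        ventilator_rate_per_min=15.0,
        ventilator_amplitude_uv=20.0 if with_ventilator else 0.0,
        sensory_paradigm=SensoryParadigm(),
    )
    return SimulationConfig(
        sampling_rate=25_000.0,
        duration_s=90.0,
        seed=seed,
        fiber_classes=[],
        electrodes=electrodes,
        noise=NoiseSpec(),
        artifacts=artifacts,
    )
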