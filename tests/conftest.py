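import numpy as np
import pytest

from ecaptools import (
    ElectrodeSpec,
    FiberClassSpec,
    NoiseSpec,
    RecruitmentSpec,
    SimulationConfig,
    StimulationTrain,
)

FS = 25_000.0


def single_channel_config(
    seed=0,
    duration_s=2.1,
    distance_m=0.05,
    velocity=50.0,
    white_rms=0.0,
    peak_uv=20.0,
    threshold_ma=1.0,
    slope=4.0,
    **electrode_kw,
):
    """One cuff channel, one fast fiber class; noiseless by default."""
    fiber = FiberClassSpec(
        name="Abeta",
        velocity_m_s=velocity,
        peak_uv=peak_uv,
        recruitment=RecruitmentSpec(threshold_ma, slope, 1.0),
    )
    ch_kw = dict(kind="cuff")
    ch_kw.update(electrode_kw)
    ch = ElectrodeSpec(id="ch0", distance_to_stim_m=distance_m,
                       noise_rms_uv=white_rms, **ch_kw)
    return SimulationConfig(
        sampling_rate=FS,
        duration_s=duration_s,
        seed=seed,
        fiber_classes=[fiber],
        electrodes=[ch],
        noise=NoiseSpec(),
    )


@pytest.fixture
def short_train():
    return StimulationTrain.regular(rate_hz=25.0, train_duration_s=2.0,
                                    amplitude_ma=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
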