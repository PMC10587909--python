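"""Referencing strategies: local-tissue vs on-nerve bipolar/tripolar.

A local-tissue reference keeps the full neural signal but also the full
common-mode stimulation artifact; on-nerve differencing cancels the
common-mode layer exactly while 'subtracting' part of a neural wave whose
wavelength exceeds the contact spacing.
"""

import numpy as np

from ecaptools import StimulationTrain, apply_reference, simulate_recording
from ecaptools.presets import cvn_ecap_config
from ecaptools.types import ElectrodeSpec

for mode in ("local_tissue", "bipolar", "tripolar"):
    cfg = cvn_ecap_config(seed=4, duration_s=1.1, with_artifact=True)
    cfg.electrodes = [ElectrodeSpec(
        id="c1", kind="cuff", distance_to_stim_m=0.05, reference=mode,
        contact_spacing_m=None if mode == "local_tissue" else 0.003,
    )]
    cfg.stim = StimulationTrain.regular(rate_hz=25.0, train_duration_s=1.0,
                                        amplitude_ma=5.0)
    rec = simulate_recording(cfg)
    out = apply_reference(rec, "c1")
    epoch = out[: int(0.010 * rec.sampling_rate)]  # first 10 ms post-pulse
    neural = rec.layers["neural"][0][: epoch.size]
    artifact = rec.layers["common_mode"][0][: epoch.size]
    print(f"{mode:>12}: epoch peak-to-peak {np.ptp(epoch):6.1f} uV "
          f"(neural layer {np.ptp(neural):5.1f} uV, "
          f"artifact layer {np.ptp(artifact):5.1f} uV)")
print("On-nerve modes cancel the artifact completely but shrink the evoked "
      "deflection; the local-tissue reference keeps the full ECAP plus the "
      "full artifact.")
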