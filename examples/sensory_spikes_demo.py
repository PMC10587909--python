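"""Detect sensory-evoked multi-unit activity in a simulated 90 s session.

The session holds 30 s quiescent / 30 s on-target stroking / 30 s off-target
stroking epochs.  The same spike train reaches all three electrodes, but a
microneurography microelectrode sees it at full amplitude while cuff and LIFE
macroelectrodes see it far below their noise floor — so the mean + 6 SD
threshold detector reports the on-target response only on the microelectrode.
"""

from ecaptools import (
    FilterSpec,
    compute_threshold,
    count_by_epoch,
    detect_spikes,
    generate_sensory_session,
    zero_phase_filter,
)
from ecaptools.presets import gan_sensory_config

rec = generate_sensory_session(gan_sensory_config(seed=8))
filt = zero_phase_filter(rec, FilterSpec(notch_enabled=True))  # asynchronous path

truth = {k: len(v) for k, v in rec.annotations["spike_times"].items()}
print(f"ground-truth spikes per epoch: {truth}")
for ch in rec.channels:
    trace = filt.channel(ch.id)
    threshold, _ = compute_threshold(trace, filt.sampling_rate, baseline_s=(1.0, 6.0))
    events = detect_spikes(trace, filt.sampling_rate, threshold, refractory_ms=1.0)
    events = count_by_epoch(events, rec.annotations["epochs"])
    print(f"{ch.id:>22}: threshold {threshold:6.2f} uV  counts "
          f"{events.per_epoch_counts}")
print("Counts on the microelectrode track the on-target epoch; macroelectrode "
      "counts stay near zero because the same spikes sit below 6 SD there.")
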