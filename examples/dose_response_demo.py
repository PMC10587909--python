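"""Build an ECAP dose-response curve end to end and extract EC10.

Simulates a 16-dose cervical-vagus session on a cuff contact (25 Hz trains,
cuff-like 2.5 uVrms noise), runs filtering -> epoching -> median averaging ->
conduction-velocity windowing -> RMS, fits a logistic growth function to the
normalized curve and prints the EC10/EC50 sensitivity points next to the
ground-truth recruitment parameters the simulator used.
"""

import numpy as np

from ecaptools import (
    DoseResponseCurve,
    FilterSpec,
    apply_velocity_tolerance,
    ecap_rms,
    epoch_align,
    extract_ecp,
    fiber_window,
    fit_logistic,
    generate_dose_response_session,
    median_average,
    normalize_curve,
    zero_phase_filter,
)
from ecaptools.presets import cvn_ecap_config

amps = np.linspace(0.0, 10.0, 16)
cfg = cvn_ecap_config(seed=42, duration_s=6.2)
cfg.electrodes = cfg.electrodes[:1]  # the cuff contact at 0.05 m

recs = generate_dose_response_session(cfg, amps, train_duration_s=6.0)
magnitudes, window = [], None
for rec in recs:
    filt = zero_phase_filter(rec, FilterSpec())
    trace = median_average(epoch_align(filt, epoch_length_ms=10.0)[0])
    if window is None and rec.events.amplitude_ma == amps.max():
        window = apply_velocity_tolerance(fiber_window(0.05, "Abeta"), trace)
    magnitudes.append(trace)
window = window or fiber_window(0.05, "Abeta")
rms = [ecap_rms(tr, window).rms_uv for tr in magnitudes]

curve = normalize_curve(DoseResponseCurve(amps, rms, channel_id="cuff_1"), 5.0)
fit = fit_logistic(curve)
r = cfg.fiber_classes[0].recruitment
truth_ec10 = r.threshold_ma - np.log(9.0) / r.slope_per_ma

print(f"Abeta window: {window.window_ms[0]:.2f}-{window.window_ms[1]:.2f} ms "
      f"(distance 0.05 m, 30-70 m/s)")
print("current (mA):", np.round(amps, 2).tolist())
print("ECAP RMS (uV):", np.round(rms, 3).tolist())
print(f"logistic fit: L={fit.L:.3f} k={fit.k:.2f}/mA x0={fit.x0:.3f} mA "
      f"y0={fit.y0:.4f}")
print(f"EC10 = {extract_ecp(fit, 10.0):.3f} mA (ground truth {truth_ec10:.3f}), "
      f"EC50 = {extract_ecp(fit, 50.0):.3f} mA (midpoint {r.threshold_ma:.1f})")
print("EC10 is the current at which the evoked response first clears 10% of "
      "saturation - the detection-threshold sensitivity of this electrode.")
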