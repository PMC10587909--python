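"""Analytic noise budget of a nerve-recording chain.

Three relationships tie the measured noise floors together: Johnson thermal
noise sqrt(4 kB T R df), the sqrt(n) reduction of uncorrelated noise under
n-sweep averaging, and the electronics' share of the total floor.
"""

from ecaptools import averaging_reduction, electronics_fraction, thermal_noise

r_ohm, t_k, df_hz = 1e6, 300.0, 2900.0
v = thermal_noise(r_ohm, t_k, df_hz) * 1e6
print(f"thermal noise of a {r_ohm/1e6:.0f} MOhm electrode over "
      f"{df_hz:.0f} Hz at {t_k:.0f} K: {v:.1f} uVrms")
print("  (an upper bound: only the real impedance generates thermal noise, "
      "so a mostly capacitive 1 MOhm microelectrode is far quieter)")

floor = 2.53  # uVrms, filtered time-series floor of a low-impedance contact
print(f"{floor} uVrms floor averaged over 750 sweeps: "
      f"{averaging_reduction(floor, 750):.2f} uVrms if fully uncorrelated")

electronics = 1.95  # uVrms, shorted-input front-end measurement
print(f"electronics share of the floor: "
      f"{electronics_fraction(electronics, floor):.0f}% "
      f"({electronics} / {floor} uVrms) - the front end, not the electrode, "
      "dominates this band")
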