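"""Dose-response curves, logistic fits and ECp sensitivity measures.

ECAP magnitude plotted against stimulation current is sigmoidal: nothing
below the recruitment threshold, progressive fiber recruitment, then
saturation.  Curves are normalized to the magnitude at a common reference
current (5 mA by default, the highest dose shared across subjects in the
emulated protocol), fitted with a four-parameter logistic
``y = y0 + L / (1 + exp(-k (x - x0)))`` by least squares, and summarized
by ECp points: the current at p% of the saturation magnitude after the
initial offset y0 is subtracted.  EC10 operationalizes the stimulation
level at which an ECAP first becomes detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize


@dataclass
class DoseResponseCurve:
    """(current mA, magnitude uVrms) points for one channel and fiber class."""

    currents_ma: np.ndarray
    magnitudes_uv: np.ndarray
    channel_id: str = ""
    fiber: str = "Abeta"
    normalized: bool = False
    normalization_current_ma: Optional[float] = None

    def __post_init__(self) -> None:
        self.currents_ma = np.asarray(self.currents_ma, dtype=float)
        self.magnitudes_uv = np.asarray(self.magnitudes_uv, dtype=float)
        if self.currents_ma.size != self.magnitudes_uv.size:
            raise ValueError("currents and magnitudes must be the same length")
        if np.unique(self.currents_ma).size != self.currents_ma.size:
            raise ValueError("dose currents must be unique")
        order = np.argsort(self.currents_ma)
        self.currents_ma = self.currents_ma[order]
        self.magnitudes_uv = self.magnitudes_uv[order]
        if np.any(self.magnitudes_uv < 0):
            raise ValueError("magnitudes must be nonnegative")


@dataclass
class LogisticFit:
    """Fitted logistic growth y = y0 + L / (1 + exp(-k (x - x0)))."""

    L: float = np.nan           # saturation magnitude above offset
    k: float = np.nan           # growth rate per mA
    x0: float = np.nan          # midpoint current, mA
    y0: float = np.nan          # initial offset (noise floor)
    residual_rms: float = np.nan
    converged: bool = False
    flat: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.y0 + self.L / (1.0 + np.exp(-self.k * (x - self.x0)))


def normalize_curve(
    curve: DoseResponseCurve,
    at_current_ma: float = 5.0,
    noise_floor_uv: float = 0.0,
) -> DoseResponseCurve:
    """Divide all magnitudes by the magnitude at the reference current.

    When the exact reference current was not tested, the nearest tested
    dose is used and recorded in ``normalization_current_ma``.  A
    normalization magnitude at or below the supplied noise floor is
    rejected (the ratio would be noise over noise).
    """
    idx = int(np.argmin(np.abs(curve.currents_ma - at_current_ma)))
    used = float(curve.currents_ma[idx])
    ref = float(curve.magnitudes_uv[idx])
    if ref <= 0 or ref <= noise_floor_uv:
        raise ValueError(
            f"normalization magnitude {ref:.4g} uVrms at {used:g} mA is not "
            f"above the noise floor ({noise_floor_uv:.4g} uVrms)"
        )
    return replace(
        curve,
        magnitudes_uv=curve.magnitudes_uv / ref,
        normalized=True,
        normalization_current_ma=used,
    )


def _logistic(x, L, k, x0, y0):
    return y0 + L / (1.0 + np.exp(-np.clip(k * (x - x0), -500, 500)))


def fit_logistic(
    curve: DoseResponseCurve,
    n_starts: int = 3,
    seed: int = 0,
    flat_rel_range: float = 0.05,
) -> LogisticFit:
    """Least-squares logistic fit with multi-start initialization.

    Initialization: y0 = min(y), L = range(y), x0 = half-range crossing,
    k = 4 / current span; two further jittered starts are tried before the
    fit is declared non-convergent.  A curve whose total range is below
    ``flat_rel_range`` of its maximum (or zero) is reported flat and
    unconverged — the signature of a non-functional channel.
    """
    x, y = curve.currents_ma, curve.magnitudes_uv
    if x.size < 5:
        raise ValueError("logistic fitting needs at least 5 dose points")
    y_rng = float(np.max(y) - np.min(y))
    if y_rng == 0.0 or y_rng < flat_rel_range * max(np.max(y), 1e-300):
        return LogisticFit(converged=False, flat=True)

    y0_init = float(np.min(y))
    half = y0_init + y_rng / 2.0
    above = np.nonzero(y >= half)[0]
    x0_init = float(x[above[0]]) if above.size else float(np.median(x))
    span = float(np.ptp(x)) or 1.0
    k_init = 4.0 / span
    rng = np.random.default_rng(seed)

    best = None
    for s in range(n_starts):
        if s == 0:
            p0 = (y_rng, k_init, x0_init, y0_init)
        else:
            p0 = (
                y_rng * rng.uniform(0.5, 1.5),
                k_init * rng.uniform(0.5, 2.0),
                x0_init + rng.uniform(-0.2, 0.2) * span,
                y0_init,
            )
        try:
            popt, _ = optimize.curve_fit(
                _logistic, x, y, p0=p0,
                bounds=([1e-12, 1e-9, -np.inf, 0.0], [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = _logistic(x, *popt) - y
        rms = float(np.sqrt(np.mean(resid**2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        return LogisticFit(converged=False)
    (L, k, x0, y0), rms = best
    return LogisticFit(L=float(L), k=float(k), x0=float(x0), y0=float(y0),
                       residual_rms=rms, converged=True)


def extract_ecp(fit: LogisticFit, p: float) -> float:
    """Current at p% of the saturation magnitude (offset-subtracted).

    Solves y(x) - y0 = (p/100) L in closed form:
    x = x0 - ln(100/p - 1) / k.  EC50 is exactly the midpoint x0.
    """
    if not fit.converged:
        raise ValueError("cannot extract ECp from a non-converged fit")
    if not (0.0 < p < 100.0):
        raise ValueError("p must be in (0, 100)")
    return float(fit.x0 - np.log(100.0 / p - 1.0) / fit.k)
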