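"""Noise-floor characterization, analytic noise budget, channel screening,
evoked heart-rate change, and cohort statistics with sequential gating.

The noise budget ties together three analytic relationships: Johnson
thermal noise V_rms = sqrt(4 k_B T R df) (real resistance only — an ideal
capacitor's imaginary impedance generates no thermal noise), the sqrt(n)
reduction of uncorrelated noise under n-sweep averaging, and the fraction
of the in-vivo noise floor attributable to the recording electronics.

Cohort comparisons follow the replicate-mean -> per-subject normalization
to a reference electrode type -> log10 -> Shapiro-Wilk check -> one-sided
t-test pipeline, with a pre-registered sequential gate: alpha is passed
down an ordered outcome list until the first null result, after which all
later outcomes are exploratory only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import constants, stats

from .ecap import ECAPTrace, FiberWindow, ecap_rms
from .filters import FilterSpec, zero_phase_filter
from .types import TimeSeriesRecording


# ---------------------------------------------------------------- noise floors

def noise_floor(
    rec: TimeSeriesRecording,
    channel_id: str,
    stage: str = "filtered",
    duration_s: float = 5.0,
    filter_spec: Optional[FilterSpec] = None,
    averaged_trace: Optional[ECAPTrace] = None,
    window: Optional[FiberWindow] = None,
) -> float:
    """Noise floor (uVrms) of one channel at a given processing stage.

    ``unfiltered`` / ``filtered``: RMS over the first ``duration_s`` seconds
    of the raw or zero-phase-filtered time series (at least 5 s required).
    ``averaged_window``: RMS of a 0 mA median-averaged trace inside the
    fiber window (pass ``averaged_trace`` and ``window``).
    """
    if stage == "averaged_window":
        if averaged_trace is None or window is None:
            raise ValueError("averaged_window stage needs averaged_trace and window")
        return ecap_rms(averaged_trace, window).rms_uv
    if stage not in ("unfiltered", "filtered"):
        raise ValueError(f"unknown noise-floor stage {stage!r}")
    n = int(round(duration_s * rec.sampling_rate))
    if rec.n_samples < n:
        raise ValueError(f"need at least {duration_s} s of data for stage {stage!r}")
    if stage == "filtered":
        rec = zero_phase_filter(rec, filter_spec or FilterSpec())
    seg = rec.channel(channel_id)[:n]
    return float(np.sqrt(np.mean(seg**2)))


def thermal_noise(
    resistance_ohm: float,
    temperature_k: float = 300.0,
    bandwidth_hz: float = 2900.0,
) -> float:
    """Johnson-noise RMS voltage (volts): sqrt(4 k_B T R df).

    Defaults: T = 300 K and the 100 Hz - 3 kHz analysis band (df = 2900 Hz).
    Only the real part of the electrode impedance belongs in R.
    """
    if temperature_k <= 0 or bandwidth_hz <= 0 or resistance_ohm < 0:
        raise ValueError("require T > 0, df > 0, R >= 0")
    return float(np.sqrt(4.0 * constants.k * temperature_k * resistance_ohm * bandwidth_hz))


def averaging_reduction(rms: float, n: int) -> float:
    """Uncorrelated-noise RMS after averaging n sweeps: rms / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(rms) / float(np.sqrt(n))


def electronics_fraction(electronics_rms: float, total_rms: float) -> float:
    """Percent of the total noise floor attributable to the electronics."""
    if total_rms == 0:
        raise ValueError("total RMS must be nonzero")
    if not (0 <= electronics_rms <= total_rms):
        raise ValueError("electronics RMS must lie in [0, total RMS]")
    return 100.0 * electronics_rms / total_rms


# ------------------------------------------------------------ channel screening

def flag_nonfunctional(
    report: pd.DataFrame,
    factor: float = 3.0,
) -> pd.DataFrame:
    """Screen channels against same-type peers.

    ``report`` needs columns ``channel``, ``kind``, ``noise_rms`` and
    optionally ``mains_rms`` and ``flat_fit`` (bool from a degenerate
    dose-response fit).  A channel is flagged when its noise RMS or mains
    RMS exceeds ``factor`` times the median of same-kind channels, or its
    dose-response is flat.  Kinds with a single channel are skipped with a
    notice column rather than screened against themselves.
    """
    report = report.copy()
    report["flagged"] = False
    report["reason"] = ""
    for kind, grp in report.groupby("kind"):
        if len(grp) < 2:
            report.loc[grp.index, "reason"] = "screening skipped: single channel of type"
            continue
        for col, label in (("noise_rms", "high noise floor"), ("mains_rms", "high mains noise")):
            if col not in grp:
                continue
            med = float(grp[col].median())
            bad = grp.index[grp[col] > factor * med]
            report.loc[bad, "flagged"] = True
            report.loc[bad, "reason"] = (
                report.loc[bad, "reason"].str.cat([label] * len(bad), sep="; ").str.lstrip("; ")
            )
        if "flat_fit" in grp:
            bad = grp.index[grp["flat_fit"].astype(bool)]
            report.loc[bad, "flagged"] = True
            report.loc[bad, "reason"] = (
                report.loc[bad, "reason"]
                .str.cat(["flat dose-response"] * len(bad), sep="; ")
                .str.lstrip("; ")
            )
    return report


# ------------------------------------------------------------------ heart rate

def evoked_hr_change(
    times_s: np.ndarray,
    hr_bpm: np.ndarray,
    stim_interval_s: tuple,
) -> float:
    """Stimulation-evoked heart-rate change (signed, bpm).

    Baseline is the mean heart rate over [stim_start - 3 s, stim_start - 1 s];
    the return value is the deviation of largest absolute value from that
    baseline during stimulation, keeping its sign (bradycardia negative).
    """
    times_s = np.asarray(times_s, dtype=float)
    hr_bpm = np.asarray(hr_bpm, dtype=float)
    t0, t1 = stim_interval_s
    pre = (times_s >= t0 - 3.0) & (times_s <= t0 - 1.0)
    if not np.any(pre) or times_s[0] > t0 - 3.0:
        raise ValueError("heart-rate trace must cover 3 s before stimulation onset")
    baseline = float(np.mean(hr_bpm[pre]))
    during = (times_s >= t0) & (times_s <= t1)
    if not np.any(during):
        raise ValueError("heart-rate trace has no samples during stimulation")
    dev = hr_bpm[during] - baseline
    return float(dev[np.argmax(np.abs(dev))])


# ------------------------------------------------------------- cohort statistics

@dataclass
class CohortResult:
    normalized: np.ndarray          # per-subject ratios (test type / reference)
    log10_values: np.ndarray
    shapiro_p: float
    t_statistic: float
    p_value: float                  # one-sided
    alpha: float
    mean: float                     # mu of normalized values
    se: float
    ci95: tuple                     # on the normalized (non-log) scale
    direction: str
    normality_warning: bool = False
    degenerate: bool = False


def cohort_compare(
    values: pd.DataFrame,
    test_type: str,
    reference_type: str,
    direction: str = "less",
    alpha: float = 0.05,
    paired: bool = False,
) -> CohortResult:
    """Compare an electrode type to a reference type across subjects.

    ``values`` needs columns ``subject``, ``kind``, ``value`` with one row
    per replicate contact.  Replicates are averaged per subject and kind,
    each subject's test-type mean is divided by its reference-type mean,
    ratios are log10-transformed, Shapiro-Wilk checks normality, and a
    one-sided t-test is run: by default a one-sample test of the log-ratios
    against 0 (``paired=True`` runs the equivalent paired two-sample test of
    log means).  ``direction='less'`` tests ratio < 1 (reference larger).
    mu, SE and the 95% t-distribution CI are reported on the ratio scale.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    means = values.groupby(["subject", "kind"])["value"].mean().unstack("kind")
    for kind in (test_type, reference_type):
        if kind not in means or means[kind].isna().any():
            raise ValueError(f"every subject needs replicate values for {kind!r}")
    if len(means) < 3:
        raise ValueError("cohort comparison needs at least 3 subjects")
    ratios = (means[test_type] / means[reference_type]).to_numpy(dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("normalized values must be positive before log10")
    logs = np.log10(ratios)

    n = logs.size
    mean = float(np.mean(ratios))
    se = float(np.std(ratios, ddof=1) / np.sqrt(n))
    tcrit = stats.t.ppf(0.975, df=n - 1)
    ci95 = (mean - tcrit * se, mean + tcrit * se)

    if np.ptp(logs) == 0.0:
        return CohortResult(
            normalized=ratios, log10_values=logs, shapiro_p=np.nan,
            t_statistic=np.nan, p_value=np.nan, alpha=alpha, mean=mean,
            se=se, ci95=ci95, direction=direction, degenerate=True,
        )

    shapiro_p = float(stats.shapiro(logs).pvalue)
    if paired:
        t_res = stats.ttest_rel(
            np.log10(means[test_type]), np.log10(means[reference_type]),
            alternative=direction,
        )
    else:
        t_res = stats.ttest_1samp(logs, 0.0, alternative=direction)
    return CohortResult(
        normalized=ratios,
        log10_values=logs,
        shapiro_p=shapiro_p,
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        alpha=alpha,
        mean=mean,
        se=se,
        ci95=ci95,
        direction=direction,
        normality_warning=shapiro_p < 0.05,
    )


def sequential_gate(outcomes: Sequence[tuple], alpha: float = 0.05) -> list:
    """Pre-registered sequential testing down an ordered outcome list.

    Each outcome is (label, p).  Outcomes are tested in order at ``alpha``;
    the first p >= alpha fails and exhausts the alpha, so every later
    outcome is exploratory only.  Returns [(label, p, status)] with status
    in {'confirmatory_pass', 'fail', 'exploratory'}.
    """
    out, exhausted = [], False
    for label, p in outcomes:
        if exhausted:
            out.append((label, p, "exploratory"))
        elif p < alpha:
            out.append((label, p, "confirmatory_pass"))
        else:
            out.append((label, p, "fail"))
            exhausted = True
    return out


def ec10_anova(table: pd.DataFrame) -> float:
    """Within-subject one-way repeated-measures ANOVA on EC10 by electrode type.

    ``table`` needs columns ``subject``, ``kind``, ``ec10``; subjects missing
    any type are dropped listwise.  A table with no within-subject variation
    across types returns p = 1.0 (F = 0) rather than NaN.
    """
    from statsmodels.stats.anova import AnovaRM

    wide = table.pivot_table(index="subject", columns="kind", values="ec10")
    wide = wide.dropna()
    if len(wide) < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 complete subjects")
    centered = wide.sub(wide.mean(axis=1), axis=0)
    if np.allclose(centered.to_numpy(), centered.to_numpy()[0], atol=1e-15):
        return 1.0  # identical type effects in every subject: F = 0
    long = wide.reset_index().melt(id_vars="subject", var_name="kind", value_name="ec10")
    res = AnovaRM(long, depvar="ec10", subject="subject", within=["kind"]).fit()
    return float(res.anova_table["Pr > F"].iloc[0])
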