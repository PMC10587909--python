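"""Noise budgeting, channel screening, evoked heart-rate change and cohort
statistics with sequential gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import constants

from ecaptools import (
    ArtifactSpec,
    averaging_reduction,
    cohort_compare,
    ec10_anova,
    electronics_fraction,
    evoked_hr_change,
    flag_nonfunctional,
    noise_floor,
    sequential_gate,
    simulate_recording,
    thermal_noise,
)
from conftest import single_channel_config


class TestNoiseFloor:
    def test_white_noise_passband_flat(self):
        """A 2.53 uVrms white floor survives band-pass filtering only
        partially (the 0.1-3 kHz band holds a fraction of the 0-12.5 kHz
        white power), but the unfiltered RMS matches the configured value."""
        cfg = single_channel_config(duration_s=5.0, white_rms=2.53)
        cfg.fiber_classes = []
        rec = simulate_recording(cfg)
        assert noise_floor(rec, "ch0", "unfiltered") == pytest.approx(2.53, rel=0.05)

    def test_zero_signal(self):
        cfg = single_channel_config(duration_s=5.0)
        cfg.fiber_classes = []
        rec = simulate_recording(cfg)
        assert noise_floor(rec, "ch0", "unfiltered") == 0.0

    def test_filtered_below_unfiltered_with_drift(self):
        cfg = single_channel_config(duration_s=6.0, white_rms=2.0)
        cfg.fiber_classes = []
        cfg.noise.drift_rms_uv = 10.0
        rec = simulate_recording(cfg)
        assert noise_floor(rec, "ch0", "filtered") < noise_floor(rec, "ch0", "unfiltered")

    def test_too_short_rejected(self):
        cfg = single_channel_config(duration_s=2.0)
        rec = simulate_recording(cfg)
        with pytest.raises(ValueError, match="5"):
            noise_floor(rec, "ch0", "unfiltered")

    def test_averaged_window_median_efficiency(self, rng):
        from ecaptools.ecap import EpochSet, fiber_window, median_average
        sigma, n = 2.53, 750
        w = fiber_window(0.05, "Abeta")
        cfg = single_channel_config(duration_s=5.0)
        rec = simulate_recording(cfg)
        got = []
        for _ in range(10):
            es = EpochSet(rng.normal(0, sigma, (n, 250)),
                          np.arange(250) / 25_000.0 * 1e3, 0.0)
            tr = median_average(es)
            got.append(
                noise_floor(rec, "ch0", "averaged_window",
                            averaged_trace=tr, window=w)
            )
        assert np.mean(got) == pytest.approx(sigma * np.sqrt(np.pi / (2 * n)),
                                             rel=0.10)


class TestNoiseBudget:
    def test_thermal_noise_worked_example(self):
        """1 MOhm at 300 K over a 2900 Hz band -> 6.9 uVrms (2 s.f.)."""
        assert thermal_noise(1e6) * 1e6 == pytest.approx(6.9, abs=0.05)

    def test_zero_resistance(self):
        assert thermal_noise(0.0) == 0.0

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.floats(1.0, 1e8), st.floats(1.0, 400.0), st.floats(1.0, 1e5))
    def test_closed_form_property(self, R, T, df):
        got = thermal_noise(R, T, df)
        expected = np.sqrt(4 * constants.k * T * R * df)
        assert got == pytest.approx(expected, rel=1e-12)
        assert thermal_noise(4 * R, T, df) == pytest.approx(2 * got, rel=1e-12)

    def test_averaging_reduction_worked_example(self):
        assert averaging_reduction(2.53, 750) == pytest.approx(0.092, abs=0.001)
        assert averaging_reduction(3.0, 1) == 3.0
        assert averaging_reduction(2.0, 4) == 1.0
        with pytest.raises(ValueError):
            averaging_reduction(1.0, 0)

    def test_electronics_fraction_worked_example(self):
        assert electronics_fraction(1.95, 2.53) == pytest.approx(77.1, abs=0.1)
        assert electronics_fraction(2.0, 2.0) == 100.0
        assert electronics_fraction(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            electronics_fraction(3.0, 2.0)
        with pytest.raises(ValueError):
            electronics_fraction(1.0, 0.0)


class TestFlagNonfunctional:
    def _report(self, noise=(2.5, 2.6, 25.0)):
        return pd.DataFrame(
            {
                "channel": ["c1", "c2", "c3"],
                "kind": ["cuff"] * 3,
                "noise_rms": noise,
                "flat_fit": [False, False, False],
            }
        )

    def test_high_noise_channel_flagged(self):
        out = flag_nonfunctional(self._report())
        assert out.set_index("channel")["flagged"].tolist() == [False, False, True]

    def test_identical_channels_unflagged(self):
        out = flag_nonfunctional(self._report(noise=(2.5, 2.5, 2.5)))
        assert not out["flagged"].any()

    def test_flat_dose_response_flagged(self):
        rep = self._report(noise=(2.5, 2.5, 2.5))
        rep.loc[1, "flat_fit"] = True
        out = flag_nonfunctional(rep)
        assert out.loc[1, "flagged"]
        assert "flat" in out.loc[1, "reason"]

    def test_single_channel_type_skipped_with_notice(self):
        rep = pd.DataFrame({"channel": ["m1"], "kind": ["microneurography"],
                            "noise_rms": [100.0]})
        out = flag_nonfunctional(rep)
        assert not out["flagged"].any()
        assert "skipped" in out.loc[0, "reason"]


class TestEvokedHrChange:
    def _t(self):
        return np.arange(0.0, 30.0, 0.05)

    def test_constant_hr_gives_zero(self):
        t = self._t()
        assert evoked_hr_change(t, np.full_like(t, 80.0), (10.0, 20.0)) == 0.0

    def test_bradycardia_negative(self):
        t = self._t()
        hr = np.where((t > 12) & (t < 18), 70.0, 80.0)
        assert evoked_hr_change(t, hr, (10.0, 20.0)) == -10.0

    def test_largest_absolute_deviation_signed(self):
        t = self._t()
        hr = np.full_like(t, 80.0)
        hr[(t > 11) & (t < 13)] = 75.0
        hr[(t > 15) & (t < 17)] = 88.0
        assert evoked_hr_change(t, hr, (10.0, 20.0)) == 8.0

    def test_missing_prestim_coverage_rejected(self):
        t = np.arange(9.5, 30.0, 0.05)
        with pytest.raises(ValueError):
            evoked_hr_change(t, np.full_like(t, 80.0), (10.0, 20.0))


def _cohort_df(rng, ratio=1.0, n_subjects=6, sigma_log10=0.3):
    rows = []
    for s in range(n_subjects):
        cuff = 10.0 * 10 ** rng.normal(0, 0.1)
        test = cuff * ratio * 10 ** rng.normal(0, sigma_log10)
        for rep in range(3):
            rows.append({"subject": s, "kind": "cuff", "value": cuff * (1 + 0.01 * rep)})
            rows.append({"subject": s, "kind": "micro", "value": test * (1 + 0.01 * rep)})
    return pd.DataFrame(rows)


class TestCohortCompare:
    def test_reference_against_itself_degenerate(self, rng):
        df = _cohort_df(rng)
        res = cohort_compare(df, "cuff", "cuff", "less")
        assert res.degenerate
        assert np.allclose(res.normalized, 1.0)
        assert np.allclose(res.log10_values, 0.0)

    def test_power_at_true_ratio_0p2(self):
        """n = 6 subjects, ratio 0.2, lognormal scatter sigma_log10 = 0.3:
        the one-sided test rejects in >= 80% of simulations."""
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            df = _cohort_df(np.random.default_rng(seed), ratio=0.2)
            res = cohort_compare(df, "micro", "cuff", "less")
            hits += res.p_value < 0.05
        assert hits / n_sim >= 0.80

    def test_type_i_error_near_5_percent(self):
        hits = 0
        n_sim = 500
        for seed in range(n_sim):
            df = _cohort_df(np.random.default_rng(10_000 + seed), ratio=1.0)
            res = cohort_compare(df, "micro", "cuff", "less")
            hits += res.p_value < 0.05
        assert hits / n_sim == pytest.approx(0.05, abs=0.025)

    def test_agrees_with_sign_permutation_test(self):
        """Rejection decisions match an exact sign-flip permutation test on
        the log ratios in >= 95% of simulated datasets."""
        agree = 0
        n_sim = 60
        for seed in range(n_sim):
            ratio = [1.0, 0.4, 0.2][seed % 3]
            df = _cohort_df(np.random.default_rng(seed), ratio=ratio)
            res = cohort_compare(df, "micro", "cuff", "less")
            logs = res.log10_values
            signs = np.array(
                [[1 if seed_ >> i & 1 else -1 for i in range(logs.size)]
                 for seed_ in range(2 ** logs.size)]
            )
            perm_means = (signs * np.abs(logs)).mean(axis=1)
            p_perm = np.mean(perm_means <= np.mean(logs))
            agree += (res.p_value < 0.05) == (p_perm < 0.05)
        assert agree / n_sim >= 0.95

    def test_nonpositive_ratio_rejected(self):
        df = pd.DataFrame(
            [{"subject": s, "kind": k, "value": 0.0 if k == "micro" else 1.0}
             for s in range(3) for k in ("cuff", "micro")]
        )
        with pytest.raises(ValueError, match="positive"):
            cohort_compare(df, "micro", "cuff", "less")


class TestSequentialGate:
    def test_four_primary_outcomes_pass(self):
        out = sequential_gate(
            [("o1", 0.002), ("o2", 0.003), ("o3", 0.01), ("o4", 0.001)]
        )
        assert [s for _, _, s in out] == ["confirmatory_pass"] * 4

    def test_fifth_null_halts_and_demotes_rest(self):
        out = sequential_gate(
            [("o1", 0.002), ("o2", 0.003), ("o3", 0.01), ("o4", 0.001),
             ("o5", 0.26), ("o6", 0.001)]
        )
        assert [s for _, _, s in out][4:] == ["fail", "exploratory"]

    def test_first_null_makes_everything_after_exploratory(self):
        out = sequential_gate([("a", 0.5), ("b", 0.001), ("c", 0.001)])
        assert [s for _, _, s in out] == ["fail", "exploratory", "exploratory"]

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_at_most_one_fail_and_nothing_after_it_confirmatory(self, ps):
        out = sequential_gate([(str(i), p) for i, p in enumerate(ps)])
        statuses = [s for _, _, s in out]
        assert statuses.count("fail") <= 1
        if "fail" in statuses:
            i = statuses.index("fail")
            assert all(s == "exploratory" for s in statuses[i + 1:])
            assert all(s == "confirmatory_pass" for s in statuses[:i])


class TestEc10Anova:
    def _table(self, shift=0.0, noise=0.05, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            base = 0.5 + 0.2 * rng.normal()
            for kind in ("cuff", "life", "micro"):
                rows.append({
                    "subject": s, "kind": kind,
                    "ec10": base + (shift if kind == "micro" else 0.0)
                    + noise * rng.normal(),
                })
        return pd.DataFrame(rows)

    def test_identical_ec10_gives_p_one(self):
        tab = pd.DataFrame([{"subject": s, "kind": k, "ec10": 0.4 + 0.1 * s}
                            for s in range(4) for k in ("cuff", "life", "micro")])
        assert ec10_anova(tab) == 1.0

    def test_power_for_10_sd_shift(self):
        hits = sum(
            ec10_anova(self._table(shift=0.5, noise=0.05, seed=s)) < 0.05
            for s in range(30)
        )
        assert hits / 30 >= 0.90

    def test_null_calibration(self):
        hits = sum(
            ec10_anova(self._table(shift=0.0, noise=0.05, seed=100 + s)) < 0.05
            for s in range(200)
        )
        assert hits / 200 == pytest.approx(0.05, abs=0.04)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ec10_anova(self._table(n=2))
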