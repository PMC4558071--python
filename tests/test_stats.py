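"""Reliability rule, sweep behaviour, median splits, paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sacpupil as sp
from sacpupil.stats import build_design, reliable_intervals


def brute_force_intervals(tv, times, threshold, min_run_ms, two_sided=True):
    """Exhaustive run enumeration: check every start index directly."""
    tv = np.asarray(tv, float)
    step = times[1] - times[0] if len(times) > 1 else 1.0
    min_run = int(np.ceil(min_run_ms / step))
    exceed = [bool(abs(v) > threshold if two_sided else v > threshold)
              and np.isfinite(v) for v in tv]
    out, i = [], 0
    while i < len(tv):
        if exceed[i]:
            j = i
            while j < len(tv) and exceed[j]:
                j += 1
            if j - i >= min_run:
                out.append((float(times[i]), float(times[j - 1] + step)))
            i = j
        else:
            i += 1
    return out


class TestReliableIntervals:
    def test_sustained_exceedance_is_one_interval(self):
        tv = np.full(250, 3.0)
        assert reliable_intervals(tv, np.arange(250.0)) == [(0.0, 250.0)]

    def test_199_sample_run_fails_200_succeeds(self):
        times = np.arange(600.0)
        for n, expect in [(199, 0), (200, 1)]:
            tv = np.zeros(600)
            tv[100:100 + n] = 3.0
            got = reliable_intervals(tv, times)
            assert len(got) == expect
            if expect:
                assert got == [(100.0, 300.0)]

    def test_negative_deflections_count_two_sided(self):
        tv = np.full(300, -2.5)
        assert reliable_intervals(tv, np.arange(300.0)) == [(0.0, 300.0)]
        assert reliable_intervals(tv, np.arange(300.0), two_sided=False) == []

    def test_nan_breaks_runs(self):
        # a single non-converged sample splits a 399-long run into two
        # sub-threshold-length pieces
        tv = np.full(399, 3.0)
        tv[199] = np.nan
        assert reliable_intervals(tv, np.arange(399.0)) == []
        # but two long-enough halves each still qualify
        tv = np.full(420, 3.0)
        tv[210] = np.nan
        assert reliable_intervals(tv, np.arange(420.0)) == [
            (0.0, 210.0), (211.0, 420.0)]

    def test_decimated_grid_scales_run_length(self):
        # 10 ms grid: 20 samples span 200 ms
        times = np.arange(0.0, 1000.0, 10.0)
        tv = np.zeros(100)
        tv[30:50] = 4.0
        assert reliable_intervals(tv, times) == [(300.0, 500.0)]
        tv[30:49] = 4.0
        tv[49] = 0.0
        assert reliable_intervals(tv, times) == []

    def test_matches_brute_force_on_random_series(self, rng):
        times = np.arange(300.0)
        for _ in range(200):
            tv = rng.choice([-4.0, -1.0, 0.0, 1.0, 4.0], size=300)
            got = reliable_intervals(tv, times, threshold=2, min_run_ms=20)
            want = brute_force_intervals(tv, times, 2, 20)
            assert got == want

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-6, 6) | st.just(float("nan")),
                    min_size=1, max_size=80),
           st.integers(1, 10))
    def test_property_matches_brute_force(self, values, min_run):
        times = np.arange(float(len(values)))
        got = reliable_intervals(np.array(values), times, 2.0, float(min_run))
        want = brute_force_intervals(values, times, 2.0, float(min_run))
        assert got == want

    def test_empty_series(self):
        assert reliable_intervals(np.array([])) == []


class TestDesign:
    def test_condition_reference_is_no_percept(self):
        f = pd.DataFrame({"condition": ["no_percept", "intrasaccadic_percept"],
                          "direction": ["left", "up"],
                          "participant": ["a", "a"]})
        X, names = build_design(f, "condition*direction")
        np.testing.assert_array_equal(X[0], [1, 0, 0, 0])
        np.testing.assert_array_equal(X[1], [1, 1, 1, 1])
        assert names[1] == "condition[percept]"

    def test_direction_nuisance_dummies(self):
        f = pd.DataFrame({"condition": ["no_percept"] * 4,
                          "direction": ["up", "down", "up", "down"],
                          "participant": ["a"] * 4})
        X, names = build_design(f, "condition+direction")
        assert names == ["Intercept", "condition[percept]", "direction[down]"]
        np.testing.assert_array_equal(X[:, 2], [0, 1, 0, 1])


def _toy_epochs(rng, n_participants=6, n_trials=8, n_times=30, effect=0.0,
                onset=10):
    """Direct epoch matrix with an optional injected condition effect."""
    rows, vals = [], []
    for p in range(n_participants):
        for tr in range(n_trials):
            cond = "intrasaccadic_percept" if tr % 2 else "no_percept"
            y = 1.0 + rng.normal(0, 0.01, n_times) + rng.normal(0, 0.005)
            if cond == "intrasaccadic_percept":
                y[onset:] -= effect
            rows.append({"participant": f"p{p}", "condition": cond,
                         "direction": "left"})
            vals.append(y)
    return np.array(vals), np.arange(n_times) * 10.0, pd.DataFrame(rows)


class TestLmeSweep:
    def test_injected_effect_recovered_with_negative_interval(self, rng):
        values, times, factors = _toy_epochs(rng, effect=0.04)
        sw = sp.lme_sweep(values, times, factors, model="condition",
                          min_run_ms=100.0)
        ivs = sw.intervals["condition[percept]"]
        assert ivs, "expected a reliable condition interval"
        i = sw.effect_names.index("condition[percept]")
        late = times >= 100.0
        assert np.nanmean(sw.coef[late, i]) == pytest.approx(-0.04, abs=0.01)

    def test_duplicated_groups_give_null_estimate(self, rng):
        values, times, factors = _toy_epochs(rng, n_times=10, effect=0.0)
        # duplicate every epoch into the other condition: exact exchangeability
        flip = {"no_percept": "intrasaccadic_percept",
                "intrasaccadic_percept": "no_percept"}
        factors2 = factors.copy()
        factors2["condition"] = factors2["condition"].map(flip)
        values = np.vstack([values, values])
        factors = pd.concat([factors, factors2], ignore_index=True)
        sw = sp.lme_sweep(values, times, factors, model="condition",
                          min_run_ms=50.0)
        i = sw.effect_names.index("condition[percept]")
        np.testing.assert_allclose(sw.coef[:, i], 0.0, atol=1e-6)
        assert sw.intervals["condition[percept]"] == []

    def test_single_participant_rejected(self, rng):
        values, times, factors = _toy_epochs(rng, n_participants=1)
        with pytest.raises(ValueError, match="participants"):
            sp.lme_sweep(values, times, factors, model="condition")

    def test_result_serializes(self, rng):
        values, times, factors = _toy_epochs(rng, n_times=6)
        sw = sp.lme_sweep(values, times, factors, model="condition",
                          min_run_ms=30.0)
        import json
        d = json.loads(sw.to_json())
        assert d["effects"] == sw.effect_names
        assert len(d["times_ms"]) == 6
        frame = sw.to_frame()
        assert set(frame["effect"]) == set(sw.effect_names)


class TestMedianSplit:
    def _df(self, vals):
        return pd.DataFrame({"participant": ["a"] * len(vals),
                             "direction": ["up"] * len(vals),
                             "metric": vals})

    def test_odd_group(self):
        out = sp.median_split_select(self._df([1.0, 2.0, 3.0]), "metric")
        assert out["metric"].tolist() == [1.0]

    def test_even_group_keeps_half(self):
        out = sp.median_split_select(self._df([1.0, 2.0, 3.0, 4.0]), "metric")
        assert out["metric"].tolist() == [1.0, 2.0]

    def test_all_equal_keeps_nothing(self):
        out = sp.median_split_select(self._df([2.0, 2.0, 2.0]), "metric")
        assert out.empty

    def test_grouping_is_per_participant_and_direction(self):
        df = pd.DataFrame({
            "participant": ["a", "a", "a", "b", "b", "b"],
            "direction": ["up"] * 6,
            "metric": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
        })
        out = sp.median_split_select(df, "metric")
        assert sorted(out["metric"]) == [1.0, 10.0]


class TestPairedT:
    def test_identical_vectors_t_zero(self):
        t, df, p = sp.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_df_is_n_minus_one(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(size=10)
        _, df, _ = sp.paired_t(a, b)
        assert df == 9

    def test_matches_textbook_formula(self):
        a = np.array([5.0, 7.0, 6.0, 9.0])
        b = np.array([4.0, 5.0, 6.0, 5.0])
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        t, df, p = sp.paired_t(a, b)
        assert t == pytest.approx(expected)
        assert df == 3

    def test_constant_nonzero_difference_errors(self):
        with pytest.raises(ValueError, match="variance"):
            sp.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestDispersion:
    def test_closed_form_sd(self):
        df = pd.DataFrame({"participant": ["a", "a"],
                           "peak": [390.0, 410.0]})
        out = sp.dispersion_metrics(df, "peak")
        assert out.loc[0, "sd"] == pytest.approx(np.sqrt(200.0))
        assert out.loc[0, "mean"] == pytest.approx(400.0)

    def test_constant_peaks_sd_zero(self):
        df = pd.DataFrame({"participant": ["a"] * 3, "peak": [400.0] * 3})
        assert sp.dispersion_metrics(df, "peak").loc[0, "sd"] == 0.0

    def test_single_trial_participant_skipped(self):
        df = pd.DataFrame({"participant": ["a", "b", "b"],
                           "peak": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning, match="skipped"):
            out = sp.dispersion_metrics(df, "peak")
        assert out["participant"].tolist() == ["b"]
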