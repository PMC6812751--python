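import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from derplab.derp import DerpTrace
from derplab.detect import (Run, find_runs, measure_component, pick_peak,
                            presence_confirmatory, presence_exploratory,
                            running_ttests)
from derplab.montage import RoiSpec
from derplab.synth import default_times


def make_derps(values, channels=("Cz",), group="meditator",
               experiment="passive"):
    """values: (subjects, channels, samples) array -> DerpTrace list."""
    values = np.asarray(values, dtype=float)
    times = (np.arange(values.shape[2]) - 50) * 2.0
    return [DerpTrace(subject=f"s{i}", group=group, experiment=experiment,
                      data=values[i], n_trials_reversal=10,
                      n_trials_stability=10, sfreq=500.0, times_ms=times,
                      channels=tuple(channels))
            for i in range(values.shape[0])]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_runs(p, alpha, min_len):
    """Enumerate all maximal sub-alpha stretches by linear scan."""
    runs, start = [], None
    for i, val in enumerate(list(p) + [np.inf]):
        if val < alpha and start is None:
            start = i
        elif not (val < alpha) and start is not None:
            if i - start >= min_len:
                runs.append((start, i - 1))
            start = None
    return runs


def brute_force_peak(window, sign):
    """Exhaustive scan over interior samples for strict local extrema."""
    best = None
    for i in range(1, len(window) - 1):
        v = window[i] * sign
        if v > window[i - 1] * sign and v > window[i + 1] * sign:
            if best is None or v > window[best] * sign:
                best = i
    return best


class TestRunningTtests:
    def test_all_zero_degenerate(self):
        derps = make_derps(np.zeros((4, 1, 451)))
        ps = running_ttests(derps, "Cz", (80, 250))
        assert np.all(ps.p == 1.0)
        assert np.all(ps.degenerate)

    def test_closed_form_oracle(self):
        """Subject values {1,2,3} at every sample: t = 2/(1/sqrt(3))."""
        vals = np.zeros((3, 1, 451))
        vals[0], vals[1], vals[2] = 1.0, 2.0, 3.0
        ps = running_ttests(make_derps(vals), "Cz", (80, 250))
        t_expected = 2.0 / (1.0 / np.sqrt(3))
        p_expected = 2 * (1 - sstats.t.cdf(t_expected, df=2))
        np.testing.assert_allclose(ps.t, t_expected)
        np.testing.assert_allclose(ps.p, p_expected)

    def test_subject_order_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 1, 451))
        a = running_ttests(make_derps(vals), "Cz", (80, 250))
        b = running_ttests(make_derps(vals[::-1]), "Cz", (80, 250))
        np.testing.assert_allclose(a.p, b.p)

    def test_degenerate_nonzero_mean(self):
        vals = np.full((4, 1, 451), 2.5)
        ps = running_ttests(make_derps(vals), "Cz", (80, 250))
        assert np.all(ps.p == 0.0) and np.all(ps.degenerate)

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            running_ttests(make_derps(np.zeros((2, 1, 451))), "Cz", (80, 250))

    def test_mixed_cell_rejected(self):
        a = make_derps(np.zeros((2, 1, 451)), group="meditator")
        b = make_derps(np.zeros((2, 1, 451)), group="non_meditator")
        with pytest.raises(ValueError, match="cell"):
            running_ttests(a + b, "Cz", (80, 250))

    def test_one_tailed_option(self):
        rng = np.random.default_rng(1)
        vals = 1.0 + rng.normal(size=(8, 1, 451))
        two = running_ttests(make_derps(vals), "Cz", (80, 250))
        greater = running_ttests(make_derps(vals), "Cz", (80, 250),
                                 tail="greater")
        pos = two.t > 0
        np.testing.assert_allclose(greater.p[pos], two.p[pos] / 2)


class TestFindRuns:
    def test_single_10_sample_run(self):
        p = np.ones(50)
        p[12:22] = 0.001
        runs = find_runs(p, 0.01, 10)
        assert len(runs) == 1
        assert (runs[0].start_index, runs[0].end_index) == (12, 21)
        assert runs[0].n_samples == 10

    def test_nine_samples_no_run(self):
        p = np.ones(50)
        p[12:21] = 0.001
        assert find_runs(p, 0.01, 10) == []

    def test_two_separated_runs_match_oracle(self):
        p = np.ones(100)
        p[10:22] = 0.001   # 12 samples
        p[50:65] = 0.005   # 15 samples
        runs = find_runs(p, 0.01, 10)
        assert [(r.start_index, r.end_index) for r in runs] \
            == brute_force_runs(p, 0.01, 10)
        assert len(runs) == 2

    def test_alpha_boundary_strict(self):
        p = np.full(30, 0.01)  # exactly alpha: not below
        assert find_runs(p, 0.01, 10) == []

    def test_run_times_reported(self):
        p = np.ones(50)
        p[5:20] = 0.0
        times = 100.0 + 2.0 * np.arange(50)
        runs = find_runs(p, 0.01, 10, times)
        assert runs[0].start_ms == 110.0 and runs[0].end_ms == 138.0

    def test_min_run_validation(self):
        with pytest.raises(ValueError):
            find_runs(np.ones(5), 0.01, 0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=60),
           st.integers(min_value=1, max_value=12))
    def test_matches_brute_force_oracle(self, p, min_len):
        p = np.asarray(p)
        runs = find_runs(p, 0.01, min_len)
        assert [(r.start_index, r.end_index) for r in runs] \
            == brute_force_runs(p, 0.01, min_len)


ROI_POS = RoiSpec("TEST", ("Cz",), 80, 250, "positive")
ROI_NEG = RoiSpec("TEST", ("Cz",), 80, 250, "negative")


class TestPickPeak:
    times5 = np.array([100.0, 102.0, 104.0, 106.0, 108.0])

    def _roi5(self, polarity):
        return RoiSpec("T", ("Cz",), 100, 108, polarity)

    def test_unique_local_maximum(self):
        pm = pick_peak(np.array([0, 1, 3, 2, 1.0]), self.times5,
                       self._roi5("positive"))
        assert pm.amplitude_uv == 3.0
        assert pm.latency_ms == 104.0
        assert not pm.fallback

    def test_monotone_ramp_falls_back_to_mean(self):
        pm = pick_peak(np.array([1, 2, 3, 4, 5.0]), self.times5,
                       self._roi5("positive"))
        assert pm.fallback
        assert pm.amplitude_uv == 3.0
        assert pm.latency_ms is None

    def test_negative_polarity(self):
        pm = pick_peak(np.array([0, -1, -4, -2, 0.0]), self.times5,
                       self._roi5("negative"))
        assert pm.amplitude_uv == -4.0
        assert pm.latency_ms == 104.0

    def test_endpoints_never_peaks(self):
        # global max at the first window sample, interior max at idx 3
        pm = pick_peak(np.array([9, 1, 0, 2, 1.0]), self.times5,
                       self._roi5("positive"))
        assert pm.amplitude_uv == 2.0
        assert pm.latency_ms == 106.0

    def test_tie_breaks_earliest(self):
        pm = pick_peak(np.array([0, 5, 0, 5, 0.0]), self.times5,
                       self._roi5("positive"))
        assert pm.latency_ms == 102.0

    def test_window_not_covered_raises(self):
        with pytest.raises(ValueError):
            pick_peak(np.zeros(5), self.times5,
                      RoiSpec("T", ("Cz",), 500, 600, "positive"))

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.floats(min_value=-10, max_value=10,
                              allow_nan=False), min_size=3, max_size=40),
           st.sampled_from(["positive", "negative"]))
    def test_matches_exhaustive_oracle(self, values, polarity):
        values = np.asarray(values)
        times = 100.0 + 2.0 * np.arange(len(values))
        roi = RoiSpec("T", ("Cz",), 100, 100 + 2 * (len(values) - 1),
                      polarity)
        pm = pick_peak(values, times, roi)
        sign = 1 if polarity == "positive" else -1
        oracle = brute_force_peak(values, sign)
        if oracle is None:
            assert pm.fallback
            assert pm.amplitude_uv == pytest.approx(values.mean())
        else:
            assert not pm.fallback
            assert pm.amplitude_uv == values[oracle]


class TestPresenceConfirmatory:
    def _signal_derps(self, amp, n=8, channels=("Cz", "Pz")):
        times = default_times()
        rng = np.random.default_rng(0)
        vals = np.zeros((n, len(channels), len(times)))
        bump = amp * np.exp(-0.5 * ((times - 160) / 25.0) ** 2)
        vals[:, 0, :] = bump + 0.3 * rng.normal(size=(n, len(times)))
        vals[:, 1, :] = 0.3 * rng.normal(size=(n, len(times)))
        return make_derps(vals, channels)

    def test_planted_component_detected(self):
        roi = RoiSpec("X", ("Cz", "Pz"), 80, 250, "positive")
        res = presence_confirmatory(self._signal_derps(4.0), roi)
        assert res.met and "Cz" in res.qualifying

    def test_all_zero_not_present(self):
        derps = make_derps(np.zeros((5, 1, 451)))
        res = presence_confirmatory(derps, ROI_POS)
        assert not res.met

    def test_monotone_in_electrodes(self):
        """Adding an electrode with a qualifying run never unmeets."""
        derps = self._signal_derps(4.0)
        narrow = RoiSpec("X", ("Pz",), 80, 250, "positive")
        wide = RoiSpec("X", ("Pz", "Cz"), 80, 250, "positive")
        res_n = presence_confirmatory(derps, narrow)
        res_w = presence_confirmatory(derps, wide)
        assert res_w.met >= res_n.met

    def test_runs_inside_window(self):
        derps = self._signal_derps(4.0)
        roi = RoiSpec("X", ("Cz",), 80, 250, "positive")
        res = presence_confirmatory(derps, roi)
        for runs in res.runs.values():
            for r in runs:
                assert 80 <= r.start_ms <= r.end_ms <= 250


class TestPresenceExploratory:
    def _derps_with_bumps(self, electrodes, bump_at, montage):
        times = default_times()
        rng = np.random.default_rng(1)
        vals = 0.25 * rng.normal(size=(8, len(electrodes), len(times)))
        bump = -4.0 * np.exp(-0.5 * ((times - 160) / 25.0) ** 2)
        for lab in bump_at:
            vals[:, electrodes.index(lab), :] += bump
        return make_derps(vals, electrodes)

    def test_adjacent_overlapping_runs_met(self, montage):
        electrodes = ("F3", "Fz", "Oz")
        derps = self._derps_with_bumps(list(electrodes), ["F3", "Fz"],
                                       montage)
        res = presence_exploratory(derps, montage, (80, 250), electrodes)
        assert res.met and ("F3", "Fz") in res.qualifying

    def test_nonadjacent_not_met(self, montage):
        electrodes = ("Fz", "Oz")
        derps = self._derps_with_bumps(list(electrodes), ["Fz", "Oz"],
                                       montage)
        res = presence_exploratory(derps, montage, (80, 250), electrodes)
        assert not res.met

    def test_single_electrode_bump_not_met(self, montage):
        electrodes = ("F3", "Fz")
        derps = self._derps_with_bumps(list(electrodes), ["Fz"], montage)
        res = presence_exploratory(derps, montage, (80, 250), electrodes)
        assert not res.met

    def test_matches_brute_force_pair_search(self, montage):
        """Oracle: scan all unordered pairs, check adjacency + overlap."""
        electrodes = ("C3", "Cz", "C4", "F3", "Fz", "F4")
        derps = self._derps_with_bumps(list(electrodes), ["Cz", "C4", "F3"],
                                       montage)
        res = presence_exploratory(derps, montage, (80, 250), electrodes)
        expected = []
        for i, a in enumerate(electrodes):
            for b in electrodes[i + 1:]:
                if frozenset((a, b)) not in montage.adjacency:
                    continue
                ra = find_runs(res.series[a].p, 0.01, 10,
                               res.series[a].times_ms)
                rb = find_runs(res.series[b].p, 0.01, 10,
                               res.series[b].times_ms)
                if any(x.overlaps(y) for x in ra for y in rb):
                    expected.append((a, b))
        assert res.qualifying == expected
        assert res.met == bool(expected)

    def test_unknown_electrode_rejected(self, montage):
        derps = make_derps(np.zeros((4, 1, 451)), ("Cz",))
        with pytest.raises(ValueError):
            presence_exploratory(derps, montage, (80, 250), ("Cz", "XX"))


class TestMeasureComponent:
    def test_row_count_and_fallback_marking(self):
        times = default_times()
        vals = np.zeros((3, 2, len(times)))
        bump = 3.0 * np.exp(-0.5 * ((times - 160) / 25.0) ** 2)
        vals[:, 0, :] = bump          # Cz: clean peak
        ramp = np.linspace(0, 1, len(times))
        vals[:, 1, :] = ramp          # Pz: no interior extremum
        derps = make_derps(vals, ("Cz", "Pz"))
        roi = RoiSpec("X", ("Cz", "Pz"), 80, 250, "positive")
        table = measure_component(derps, roi)
        assert len(table) == 3 * 2
        cz = table[table.electrode == "Cz"]
        assert (~cz.fallback).all()
        np.testing.assert_allclose(cz.latency_ms, 160.0, atol=2)
        pz = table[table.electrode == "Pz"]
        assert pz.fallback.all()
        assert pz.latency_ms.isna().all()

    def test_noiseless_latency_recovery(self):
        times = default_times()
        vals = np.zeros((4, 1, len(times)))
        for i in range(4):
            vals[i, 0] = -2.0 * np.exp(-0.5 * ((times - (160 + 2 * i))
                                               / 25.0) ** 2)
        derps = make_derps(vals, ("Cz",))
        roi = RoiSpec("FN", ("Cz",), 80, 250, "negative")
        table = measure_component(derps, roi)
        np.testing.assert_allclose(
            sorted(table.latency_ms), [160, 162, 164, 166])


class TestSpecificity:
    """False-positive behaviour of the liberal presence criterion."""

    N_SIM = 500

    def _rates(self):
        from derplab.preprocess import lowpass
        rng = np.random.default_rng(99)
        roi = RoiSpec("X", ("E1", "E2", "E3", "E4", "E5", "E6"),
                      80, 250, "positive")
        hits_white = hits_filtered = 0
        for _ in range(self.N_SIM):
            white = rng.normal(size=(12, 6, 451))
            filtered = lowpass(white, 25.0, 500.0)
            for vals, bucket in ((white, "w"), (filtered, "f")):
                res = presence_confirmatory(
                    make_derps(vals, roi.electrodes), roi)
                if res.met:
                    if bucket == "w":
                        hits_white += 1
                    else:
                        hits_filtered += 1
        return hits_white / self.N_SIM, hits_filtered / self.N_SIM

    def test_false_positive_rates(self):
        rate_white, rate_filtered = self._rates()
        # The run-length criterion is near-immune to independent noise but
        # clearly liberal once noise is autocorrelated (filtered).
        assert rate_filtered > 0.01, (
            f"filtered-noise rate {rate_filtered} not above per-test alpha")
        assert rate_white <= rate_filtered
        print(f"\nconfirmatory criterion false-positive rate over "
              f"{self.N_SIM} pure-noise simulations: "
              f"white={rate_white:.3f}, filtered={rate_filtered:.3f}")
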