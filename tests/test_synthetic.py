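"""Generator: presets, CTMC statistics, photophysics, rendering, determinism."""

import numpy as np
import pytest
from scipy import stats

import ribofret as rf
from ribofret.synthetic import (AcquisitionParams, PhotophysicsParams,
                                StatePath, apply_photophysics, build_preset,
                                generate_dataset, render_trace,
                                simulate_state_path)
from conftest import make_noiseless_scheme


class TestPresets:
    def test_xl_preset_has_tabulated_stalled_intermediate_rates(self):
        p = build_preset("XL")
        i, j = p.scheme.index_of("0.6"), p.scheme.index_of("0.4")
        assert p.scheme.rate_matrix[i, j] == pytest.approx(7.9)
        assert p.scheme.rate_matrix[j, i] == pytest.approx(1.2)

    def test_pre_preset_is_half_static(self):
        assert build_preset("PRE").static_fraction == 0.5

    def test_post_preset_is_single_static_state(self):
        p = build_preset("POST")
        assert p.scheme.n_states == 1
        assert p.scheme.fret_mean[0] == pytest.approx(0.24)
        assert np.all(p.scheme.rate_matrix == 0)

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="XL"):
            build_preset("nope")

    @pytest.mark.parametrize("name", rf.PRESET_NAMES)
    def test_all_presets_have_valid_initial_distribution(self, name):
        p = build_preset(name)
        pi = p.scheme.initial_distribution()
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi >= 0)


class TestStatePathSimulation:
    def test_symmetric_two_state_occupancy_is_half(self):
        scheme = make_noiseless_scheme(["a", "b"], [0.8, 0.6],
                                       {("a", "b"): 3.0, ("b", "a"): 3.0})
        path = simulate_state_path(scheme, 2000.0, rng=1)
        occ = np.bincount(path.states, weights=path.sojourn_durations(),
                          minlength=2) / path.duration
        n = len(path.states)
        se = 0.5 / np.sqrt(n / 2)   # conservative per-state SE
        assert abs(occ[0] - 0.5) < 3 * se

    def test_asymmetric_occupancy_matches_stationary_distribution(self):
        # brute-force linear-algebra stationary solution as the oracle
        scheme = make_noiseless_scheme(["hi", "lo"], [0.6, 0.4],
                                       {("hi", "lo"): 7.9, ("lo", "hi"): 1.2})
        q = scheme.generator()
        pi = scheme.stationary_distribution()
        assert pi @ q == pytest.approx(np.zeros(2), abs=1e-12)
        total = 0.0
        occ = np.zeros(2)
        n_sojourns = 0
        for seed in range(5):
            path = simulate_state_path(scheme, 4000.0, rng=seed)
            occ += np.bincount(path.states, weights=path.sojourn_durations(),
                               minlength=2)
            total += path.duration
            n_sojourns += len(path.states)
        ratio = occ[1] / occ[0]
        expected = pi[1] / pi[0]        # = k12/k21 ~ 6.58
        se = expected * 3.0 / np.sqrt(n_sojourns)
        assert abs(ratio - expected) < 3 * max(se, 0.05 * expected)

    def test_zero_duration_rejected_and_absorbing_is_single_sojourn(self):
        scheme = make_noiseless_scheme(["only"], [0.5], {})
        with pytest.raises(ValueError):
            simulate_state_path(scheme, 0.0, rng=0)
        path = simulate_state_path(scheme, 0.033, rng=0)
        assert len(path.states) == 1

    def test_dwell_durations_are_exponential(self):
        scheme = make_noiseless_scheme(["a", "b"], [0.6, 0.4],
                                       {("a", "b"): 4.0, ("b", "a"): 4.0})
        path = simulate_state_path(scheme, 30000.0, rng=3)
        d = path.sojourn_durations()[:-1]     # last sojourn is truncated
        _, p = stats.kstest(d, "expon", args=(0, 0.25))
        assert p > 0.01

    def test_reproducible_under_fixed_seed(self, two_state_scheme):
        a = simulate_state_path(two_state_scheme, 33.0, rng=9)
        b = simulate_state_path(two_state_scheme, 33.0, rng=9)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.entry_times, b.entry_times)


class TestPhotophysics:
    def test_zero_rates_mean_no_events(self):
        ev = apply_photophysics(PhotophysicsParams(0.0, 0.0), 33.0, rng=0)
        assert ev.donor_bleach_time is None
        assert ev.acceptor_bleach_time is None
        assert ev.blink_intervals == ()

    def test_bleach_times_have_exponential_mean(self):
        params = PhotophysicsParams(bleach_rate_donor=0.1,
                                    bleach_rate_acceptor=0.0)
        rng = np.random.default_rng(4)
        times = []
        for _ in range(10_000):
            ev = apply_photophysics(params, 1e9, rng=rng)
            times.append(ev.donor_bleach_time)
        assert np.mean(times) == pytest.approx(10.0, rel=0.05)


class TestRenderTrace:
    def _render(self, scheme, path, photo, acq, rng=0):
        from ribofret.synthetic import PhotophysicsEvents
        events = PhotophysicsEvents(None, None)
        return render_trace(path, events, scheme, photo, acq, rng=rng)

    def test_noiseless_single_state_splits_brightness_by_fret(
            self, noiseless_photophysics):
        scheme = make_noiseless_scheme(["s"], [0.5], {})
        acq = AcquisitionParams(0.033, 0.33)
        path = StatePath(np.array([0]), np.array([0.0]), 0.33)
        raw, truth = self._render(scheme, path, noiseless_photophysics, acq)
        assert raw.donor == pytest.approx(np.full(10, 500.0))
        assert raw.acceptor == pytest.approx(np.full(10, 500.0))

    def test_bleedthrough_adds_exact_fraction_of_donor_signal(self):
        scheme = make_noiseless_scheme(["s"], [0.5], {})
        photo = PhotophysicsParams(0.0, 0.0, bleedthrough=0.13, noise_sd=0.0)
        acq = AcquisitionParams(0.033, 0.33)
        path = StatePath(np.array([0]), np.array([0.0]), 0.33)
        raw, _ = self._render(scheme, path, photo, acq)
        assert raw.acceptor == pytest.approx(500.0 + 0.13 * 500.0)

    def test_midframe_transition_renders_time_weighted_fret(
            self, noiseless_photophysics):
        scheme = make_noiseless_scheme(["hi", "lo"], [0.8, 0.6], {})
        acq = AcquisitionParams(frame_interval=0.1, observation_window=0.1)
        path = StatePath(np.array([0, 1]), np.array([0.0, 0.05]), 0.1)
        raw, _ = self._render(scheme, path, noiseless_photophysics, acq)
        e = raw.acceptor[0] / (raw.donor[0] + raw.acceptor[0])
        assert e == pytest.approx(0.7)

    def test_acceptor_bleach_dequenches_donor(self, noiseless_photophysics):
        from ribofret.synthetic import PhotophysicsEvents
        scheme = make_noiseless_scheme(["s"], [0.8], {})
        acq = AcquisitionParams(0.033, 0.33)
        path = StatePath(np.array([0]), np.array([0.0]), 0.33)
        events = PhotophysicsEvents(None, acceptor_bleach_time=5 * 0.033)
        raw, truth = render_trace(path, events, scheme,
                                  noiseless_photophysics, acq, rng=0)
        assert raw.acceptor[-1] == pytest.approx(0.0)
        assert raw.donor[-1] == pytest.approx(1000.0)   # anti-correlated rise
        assert raw.donor[0] == pytest.approx(200.0)
        assert truth.bleach_frame_acceptor == 5


class TestGenerateDataset:
    def test_static_fraction_matches_binomial_draw(self):
        ds = generate_dataset("PRE", 1000, seed=2)
        frac = ds.truth_traces["is_static"].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_single_trace_dataset_is_valid(self):
        ds = generate_dataset("POST", 1, seed=0)
        assert ds.traces["trace_id"].nunique() == 1
        assert len(ds.truth_traces) == 1

    def test_same_seed_gives_identical_output(self, tmp_path):
        import ribofret.io as rio
        a = generate_dataset("XL", 5, seed=99)
        b = generate_dataset("XL", 5, seed=99)
        pa, pb = tmp_path / "a", tmp_path / "b"
        a.save(pa)
        b.save(pb)
        for name in ("traces.tsv", "ground_truth_frames.tsv",
                     "ground_truth_traces.tsv"):
            assert rio.file_checksum(pa / name) == rio.file_checksum(pb / name)

    def test_n_traces_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_dataset("PRE", 0, seed=1)

    def test_noiseless_rendering_matches_true_fret_exactly(
            self, noiseless_photophysics):
        # full round trip: rendered channels invert to the ground-truth
        # occupancy-weighted FRET at machine precision
        from ribofret.synthetic import ConditionPreset
        from ribofret.trace_qc import compute_fret, correct_bleedthrough
        scheme = make_noiseless_scheme(
            ["0.6", "0.4"], [0.56, 0.40], {("0.6", "0.4"): 7.9,
                                           ("0.4", "0.6"): 1.2})
        preset = ConditionPreset(name="test", scheme=scheme)
        ds = generate_dataset(preset, 3, seed=5,
                              photophysics=noiseless_photophysics)
        truth = ds.truth_frames
        for raw in ds.raw_traces():
            fret = compute_fret(correct_bleedthrough(raw, 0.0))
            expected = truth.loc[truth.trace_id == raw.trace_id,
                                 "true_fret"].to_numpy()
            assert fret.efficiency == pytest.approx(expected, abs=1e-12)
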