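"""Quality control: corrections, smoothing, bleach steps, selection."""

import numpy as np
import pytest

import ribofret as rf
from ribofret.trace_qc import (QCRules, RawTrace, check_anticorrelation,
                               compute_fret, correct_bleedthrough,
                               detect_bleach_steps, select_and_truncate,
                               smooth)
from conftest import make_noiseless_scheme


def _trace(donor, acceptor, dt=0.033, tid="t"):
    return RawTrace(tid, np.asarray(donor, float), np.asarray(acceptor, float), dt)


class TestBleedthrough:
    def test_subtracts_fraction_of_donor(self):
        t = _trace([100.0] * 12, [50.0] * 12)
        out = correct_bleedthrough(t, 0.13)
        assert out.acceptor == pytest.approx(np.full(12, 37.0))
        assert out.donor == pytest.approx(t.donor)

    def test_zero_beta_is_identity(self):
        t = _trace([100.0] * 12, [50.0] * 12)
        assert correct_bleedthrough(t, 0.0).acceptor == pytest.approx(t.acceptor)

    @pytest.mark.parametrize("beta", [-0.1, 1.0, 1.5])
    def test_invalid_beta_rejected(self, beta):
        with pytest.raises(ValueError):
            correct_bleedthrough(_trace([1] * 12, [1] * 12), beta)

    def test_roundtrip_against_renderer(self, noiseless_photophysics):
        from dataclasses import replace
        from ribofret.synthetic import ConditionPreset, generate_dataset
        photo = replace(noiseless_photophysics, bleedthrough=0.13)
        scheme = make_noiseless_scheme(["a", "b"], [0.7, 0.3],
                                       {("a", "b"): 2.0, ("b", "a"): 2.0})
        ds = generate_dataset(ConditionPreset(name="x", scheme=scheme), 2,
                              seed=1, photophysics=photo)
        for raw in ds.raw_traces():
            corrected = correct_bleedthrough(raw, 0.13)
            # pre-bleed acceptor signal is brightness * E
            e = ds.truth_frames.loc[ds.truth_frames.trace_id == raw.trace_id,
                                    "true_fret"].to_numpy()
            assert corrected.acceptor == pytest.approx(1000.0 * e, abs=1e-9)


class TestSmooth:
    def test_three_point_average(self):
        assert smooth(np.array([0.0, 3.0, 6.0]), 3)[1] == pytest.approx(3.0)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        assert smooth(x, 1) == pytest.approx(x)

    def test_constant_series_unchanged(self):
        assert smooth(np.full(20, 2.5), 3) == pytest.approx(np.full(20, 2.5))

    def test_mean_preserved_up_to_edges(self, rng):
        x = rng.normal(size=500)
        assert smooth(x, 3).mean() == pytest.approx(x.mean(), abs=0.01)

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.arange(10.0), 2)
        with pytest.raises(ValueError):
            smooth(np.arange(4.0), 5)


class TestBleachSteps:
    def _noisy_step(self, rng, level, frame, n=300, noise=30.0):
        x = np.full(n, level) + rng.normal(0, noise, n)
        x[frame:] = rng.normal(0, noise, n - frame)
        return x

    def test_acceptor_drop_to_background_is_detected(self, rng):
        d = np.full(300, 500.0) + rng.normal(0, 30, 300)
        a = self._noisy_step(rng, 480.0, 120)
        steps = detect_bleach_steps(_trace(d, a))
        assert [c for c, _ in steps] == ["acceptor"]
        assert abs(steps[0][1] - 120) <= 2

    def test_no_drop_gives_empty_list(self, rng):
        d = np.full(300, 500.0) + rng.normal(0, 30, 300)
        a = np.full(300, 480.0) + rng.normal(0, 30, 300)
        assert detect_bleach_steps(_trace(d, a)) == []

    def test_partial_then_full_drop_counts_two_steps(self, rng):
        # double-labelled spot: donor at 2x brightness, then 1x, then dark
        d = np.concatenate([np.full(100, 2000.0), np.full(100, 1000.0),
                            np.zeros(100)]) + rng.normal(0, 30, 300)
        a = np.full(300, 200.0) + rng.normal(0, 30, 300)
        steps = detect_bleach_steps(_trace(d, a))
        donor_steps = [f for c, f in steps if c == "donor"]
        assert len(donor_steps) == 2
        _, reports = select_and_truncate([_trace(d, a)])
        assert reports[0].rejection_reason == "multi_step_bleach"

    def test_fret_transition_is_not_a_bleach_step(self, rng):
        # large anti-correlated change that does not land at background
        d = np.concatenate([np.full(150, 240.0), np.full(150, 760.0)])
        a = np.concatenate([np.full(150, 760.0), np.full(150, 240.0)])
        d = d + rng.normal(0, 30, 300)
        a = a + rng.normal(0, 30, 300)
        assert detect_bleach_steps(_trace(d, a)) == []


class TestAnticorrelation:
    def test_perfectly_anticorrelated_channels(self):
        x = np.sin(np.linspace(0, 10, 100))
        assert check_anticorrelation(_trace(500 + 100 * x, 500 - 100 * x)) \
            == pytest.approx(-1.0)

    def test_independent_noise_is_near_zero(self, rng):
        r = check_anticorrelation(_trace(rng.normal(500, 50, 2000),
                                         rng.normal(500, 50, 2000)))
        assert abs(r) < 0.1

    def test_constant_channel_is_undefined(self):
        assert np.isnan(check_anticorrelation(_trace([5.0] * 20,
                                                     [1.0, 2.0] * 10)))

    def test_simulated_dynamic_traces_pass_threshold_over_prebleach_window(self):
        ds = rf.generate_dataset("XL", 12, seed=4)
        _, reports = select_and_truncate(ds.raw_traces())
        accepted = [r for r in reports if r.accepted]
        assert len(accepted) >= 8
        assert all(r.anticorrelation < -0.3 for r in accepted)


class TestComputeFret:
    @pytest.mark.parametrize("d,a,e", [(200.0, 200.0, 0.5),
                                       (300.0, 100.0, 0.25),
                                       (0.0, 400.0, 1.0)])
    def test_ratio_definition(self, d, a, e):
        out = compute_fret(_trace([d] * 12, [a] * 12))
        assert out.efficiency == pytest.approx(np.full(12, e))

    def test_invalid_frames_flagged_and_rejected_beyond_threshold(self):
        d = np.full(100, 100.0)
        a = np.full(100, 100.0)
        d[:4] = -100.0
        a[:4] = 50.0     # 4% of frames invalid: kept, flagged NaN
        out = compute_fret(_trace(d, a))
        assert np.isnan(out.efficiency[:4]).all()
        d[:10] = -100.0
        a[:10] = 50.0    # 10% invalid: trace rejected
        assert compute_fret(_trace(d, a)) is None


class TestSelectAndTruncate:
    def test_short_acceptor_lifetime_rejected(self, rng):
        d = np.full(300, 500.0) + rng.normal(0, 30, 300)
        a = self._step(rng, 480.0, 8)
        _, reports = select_and_truncate([_trace(d, a)])
        assert not reports[0].accepted
        assert reports[0].rejection_reason == "short_lifetime"

    def _step(self, rng, level, frame, n=300, noise=30.0):
        x = np.full(n, level) + rng.normal(0, noise, n)
        x[frame:] = rng.normal(0, noise, n - frame)
        return x

    def test_clean_bleach_truncates_at_step(self, rng):
        ds = rf.generate_dataset("PRE", 20, seed=8)
        fret, reports = select_and_truncate(ds.raw_traces())
        for rep in reports:
            if rep.accepted:
                assert rep.truncated_length >= 10
        accepted_ids = {t.trace_id for t in fret}
        assert {r.trace_id for r in reports if r.accepted} == accepted_ids

    def test_every_rejection_has_a_reason(self):
        ds = rf.generate_dataset("XL", 30, seed=9)
        _, reports = select_and_truncate(ds.raw_traces())
        assert all(r.rejection_reason is not None
                   for r in reports if not r.accepted)
        assert len(reports) == 30

    def test_noiseless_qc_chain_reproduces_ground_truth_exactly(
            self, noiseless_photophysics):
        # order of operations check: with smoothing disabled the accepted
        # FRET traces equal the ground-truth time-weighted FRET
        from dataclasses import replace
        from ribofret.synthetic import ConditionPreset, generate_dataset
        photo = replace(noiseless_photophysics, bleedthrough=0.13)
        scheme = make_noiseless_scheme(["a", "b"], [0.7, 0.3],
                                       {("a", "b"): 2.0, ("b", "a"): 2.0})
        ds = generate_dataset(ConditionPreset(name="x", scheme=scheme), 3,
                              seed=2, photophysics=photo)
        rules = QCRules(smooth_window=1, anticorrelation_threshold=None)
        fret, reports = select_and_truncate(ds.raw_traces(), rules)
        assert all(r.accepted for r in reports)
        for t in fret:
            e_true = ds.truth_frames.loc[
                ds.truth_frames.trace_id == t.trace_id,
                "true_fret"].to_numpy()[:len(t)]
            assert t.efficiency == pytest.approx(e_true, abs=1e-9)
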