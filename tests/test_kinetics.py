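"""Dwell extraction, exponential fits, bleach rates and corrections."""

import numpy as np
import pytest

import ribofret as rf
from ribofret.kinetics import (back_calculate_reverse_rate, correct_rates,
                               estimate_bleach_rate, extract_dwells,
                               fit_exponential, rate_from_tau)
from ribofret.trace_qc import QCReport
from test_transitions import make_ideal

DT = 0.033


class TestExtractDwells:
    def test_example_pattern_complete_and_censored(self):
        ideal = make_ideal([0.6] * 10 + [0.4] * 20 + [0.6] * 15)
        reports = [QCReport("t", True, None, bleach_frame=45,
                            truncated_length=45)]
        dwells = extract_dwells([ideal], reports)
        assert len(dwells) == 3
        first, second, last = dwells
        assert (first.state_class, first.terminated_by,
                first.destination_class) == ("0.6", "transition", "0.4")
        assert first.duration == pytest.approx(10 * DT)
        assert second.duration == pytest.approx(20 * DT)
        assert last.terminated_by == "bleach"
        assert last.destination_class is None

    def test_static_trace_is_single_censored_dwell(self):
        dwells = extract_dwells([make_ideal([0.8] * 60)])
        assert len(dwells) == 1
        assert dwells[0].terminated_by == "trace_end"

    def test_dwells_tile_the_analyzed_window(self, rng):
        levels = np.repeat(rng.choice([0.6, 0.4], size=30),
                           rng.integers(2, 20, size=30))
        ideal = make_ideal(levels)
        dwells = extract_dwells([ideal])
        assert sum(d.duration for d in dwells) == pytest.approx(
            len(levels) * DT)


class TestFitExponential:
    def test_large_sample_tau_recovery(self, rng):
        d = rng.exponential(0.25, 10_000)
        fit = fit_exponential(d, DT, t_min=0.0)
        assert fit.tau == pytest.approx(0.25, rel=0.10)

    def test_frame_quantized_dwells_recovered(self, rng):
        # durations quantized to whole frames at 33 ms, tau = 0.125 s
        d = np.ceil(rng.exponential(0.125, 20_000) / DT) * DT
        d = d[d >= 2 * DT]
        fit = fit_exponential(d, DT)
        assert fit.tau == pytest.approx(0.125, rel=0.15)

    def test_rate_vs_mean_reciprocal_consistency(self, rng):
        d = rng.exponential(0.4, 2000) + 2 * DT   # shifted, memoryless
        fit = fit_exponential(d, DT)
        k_fit = rate_from_tau(fit)
        k_mean = 1.0 / (np.mean(d) - 2 * DT)
        assert k_fit == pytest.approx(k_mean, rel=0.10)

    def test_identical_dwells_flagged_degenerate(self):
        fit = fit_exponential(np.full(50, 5 * DT), DT)
        assert "degenerate" in fit.flags

    def test_too_few_dwells_refused(self):
        with pytest.raises(ValueError):
            fit_exponential(np.array([0.1] * 5), DT)


class TestRateFromTau:
    @pytest.mark.parametrize("tau,k", [(0.125, 8.0), (1.0, 1.0),
                                       (0.127, 7.87)])
    def test_reciprocal(self, tau, k):
        from ribofret.kinetics import ExpFit
        fit = ExpFit(0.0, 1.0, tau, 0.0, 100)
        assert rate_from_tau(fit) == pytest.approx(k, abs=0.01)


class TestBleachRate:
    def test_censored_mle_recovers_simulated_rate(self, rng):
        # 1000 traces, bleach 0.1 /s, observation window 33 s
        n_frames = 1000
        reports = []
        for i in range(1000):
            t = rng.exponential(10.0)
            frame = int(t / DT)
            if frame < n_frames:
                reports.append(QCReport(str(i), True, None, frame, frame))
            else:
                reports.append(QCReport(str(i), True, None, None, n_frames))
        k = estimate_bleach_rate(reports, DT)
        assert k == pytest.approx(0.1, rel=0.10)

    def test_mean_trace_length_ten_seconds_gives_point_one(self, pre_dataset):
        # default photophysics: 0.05 + 0.05 per dye
        _, reports = rf.select_and_truncate(pre_dataset.raw_traces())
        k = estimate_bleach_rate([r for r in reports if r.accepted], DT)
        assert k == pytest.approx(0.1, rel=0.35)

    def test_no_events_refused(self):
        reports = [QCReport("a", True, None, None, 500)]
        with pytest.raises(ValueError):
            estimate_bleach_rate(reports, DT)


class TestCorrectRates:
    def test_zero_bleach_and_dead_time_is_identity(self):
        k_obs = {("0.6", "0.4"): 4.0, ("0.4", "0.6"): 1.0}
        out = correct_rates(k_obs, 0.0, dead_time=0.0)
        assert out == pytest.approx(k_obs)

    def test_competing_bleach_subtracted(self, rng):
        # competing exponentials: transition 4.0 /s vs bleach 0.3 /s;
        # observed dwell rate is the sum, correction recovers the truth
        n = 20_000
        t_trans = rng.exponential(1 / 4.0, n)
        t_bleach = rng.exponential(1 / 0.3, n)
        observed = np.minimum(t_trans, t_bleach)
        complete = observed[t_trans < t_bleach]
        k_obs = 1.0 / complete.mean()
        out = correct_rates({("a", "b"): k_obs}, 0.3, dead_time=0.0)
        assert out[("a", "b")] == pytest.approx(4.0, rel=0.05)

    def test_small_relative_difference_when_bleach_is_slow(self):
        out = correct_rates({("a", "b"): 8.0}, 0.1, dead_time=0.0)
        assert abs(out[("a", "b")] - 8.0) / 8.0 < 0.03

    def test_bleach_dominating_is_floored_not_negative(self):
        out = correct_rates({("a", "b"): 0.5}, 2.0, dead_time=0.0)
        assert out[("a", "b")] > 0

    def test_dead_time_divides_by_destination_survival(self):
        k_obs = {("a", "b"): 2.0, ("b", "a"): 6.0}
        out = correct_rates(k_obs, 0.0, dead_time=0.05)
        # self-consistent: p_b = exp(-k_b_exit * t_d) with corrected exits
        p_b = np.exp(-out[("b", "a")] * 0.05)
        assert out[("a", "b")] == pytest.approx(2.0 / p_b, rel=1e-6)

    def test_static_adjustment_downweights(self):
        base = correct_rates({("a", "b"): 2.0}, 0.0, 0.0)
        adj = correct_rates({("a", "b"): 2.0}, 0.0, 0.0, n_static=50,
                            n_dynamic=50, t_eff=10.0, static_adjustment=True)
        assert adj[("a", "b")] < base[("a", "b")]


class TestReverseRate:
    @pytest.mark.parametrize("kf,keq,expected", [
        (7.9, 6.7, 1.2), (6.9, 15.3, 0.5),
    ])
    def test_footnote_back_calculation(self, kf, keq, expected):
        assert back_calculate_reverse_rate(kf, keq) == pytest.approx(
            expected, abs=0.05)

    def test_unity_keq_is_identity(self):
        assert back_calculate_reverse_rate(3.3, 1.0) == 3.3


class TestRateTable:
    def test_xl_summary_row(self, xl_analysis):
        _, res = xl_analysis
        row = res.rate_table.iloc[0]
        assert row["state_high"] == "0.6"
        assert row["state_low"] == "0.4"
        assert row["P_high"] + row["P_low"] == pytest.approx(1.0)
        assert row["Keq"] == pytest.approx(row["P_low"] / row["P_high"])
        assert row["dG_kBT"] == pytest.approx(-np.log(row["Keq"]))
        assert row["n_down"] > 100

    def test_post_dataset_has_single_population_no_rates(self):
        ds = rf.generate_dataset("POST", 30, seed=3)
        res = rf.analyze(ds.raw_traces(), rf.PipelineConfig(k_max=2, seed=3),
                         condition="POST")
        row = res.rate_table.iloc[0]
        assert row["state_low"] is None
        assert row["Keq"] is None
        assert res.rates == []

    def test_detailed_balance_on_equilibrium_simulation(self):
        # k_f / (k_r * K_eq) should be near 1 for a reversible two-state
        # chain; both the rates and the populations come from the pipeline
        from ribofret.synthetic import ConditionPreset, KineticScheme
        scheme = KineticScheme(("0.6", "0.4"), np.array([0.56, 0.40]),
                               np.array([0.08, 0.09]),
                               np.array([[0.0, 2.5], [1.5, 0.0]]))
        ds = rf.generate_dataset(ConditionPreset(name="eq", scheme=scheme),
                                 200, seed=55)
        res = rf.analyze(ds.raw_traces(),
                         rf.PipelineConfig(k_max=3, seed=3,
                                           sync_populations="never"),
                         condition="eq")
        row = res.rate_table.iloc[0]
        assert row["balance"] == pytest.approx(1.0, abs=0.35)
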