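"""Dwell-time kinetics with photobleaching and missed-event corrections.

Dwell times per canonical state are taken from filtered idealized
trajectories; complete dwells (ending in a transition) are binned at the
frame interval and fitted with y = y0 + A*exp(-t/tau); observed rates are
1/tau apportioned over the destinations of the state's transitions.

Observed rates are biased in two ways. Photobleaching terminates dwells,
adding its rate to every observed exit rate, so the bleach rate is
subtracted. Second, the transition filters cannot see sojourns shorter
than about the minimum dwell, so visits to fast states are missed and the
flanking dwells coalesce; the correction divides each branch rate by the
probability that a destination sojourn survives the effective dead time,
solved self-consistently across states. An optional adjustment
down-weights rates for the possibility that apparently static traces are
slow dynamic ones; it is off by default because in the simulated
conditions static traces are a structurally distinct sub-population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .idealization import CanonicalMap, IdealizedTrace, LT_CANONICAL
from .trace_qc import QCReport
from .transitions import segment_trace, MIN_DELTA, MIN_DWELL_FRAMES

__all__ = [
    "DwellRecord",
    "ExpFit",
    "RateEstimate",
    "OBSERVATION_TIME",
    "extract_dwells",
    "fit_exponential",
    "rate_from_tau",
    "estimate_bleach_rate",
    "correct_rates",
    "estimate_rates",
    "back_calculate_reverse_rate",
    "summarize_rate_table",
]

OBSERVATION_TIME = 33.0     # s, camera observation window T
MIN_DWELLS_FOR_FIT = 20


@dataclass(frozen=True)
class DwellRecord:
    trace_id: str
    state_class: str | None
    duration: float                      # s
    terminated_by: Literal["transition", "bleach", "trace_end"]
    destination_class: str | None = None


@dataclass(frozen=True)
class ExpFit:
    """y = y0 + A*exp(-t/tau) fitted to a binned dwell histogram."""

    y0: float
    amplitude: float
    tau: float
    tau_stderr: float
    n_dwells: int
    flags: tuple[str, ...] = ()


@dataclass
class RateEstimate:
    from_class: str
    to_class: str
    k_obs: float                # branch-apportioned observed rate, 1/s
    k_corr: float               # after bleach + missed-event correction
    n_transitions: int
    k_bleach_state: float
    tau_fit: ExpFit | None = None
    flags: tuple[str, ...] = ()


def extract_dwells(
    ideals: Iterable[IdealizedTrace],
    qc_reports: Iterable[QCReport] | None = None,
    min_delta: float = MIN_DELTA,
    min_dwell: int = MIN_DWELL_FRAMES,
) -> list[DwellRecord]:
    """All dwells of the filtered trajectories.

    The final dwell of each trace is censored: it ends by photobleaching
    (when QC recorded a bleach step) or by the end of the record, and it
    carries no destination. Complete and censored dwells together tile
    each trace's analyzed window exactly.
    """
    bleached = {}
    for rep in qc_reports or []:
        bleached[rep.trace_id] = rep.bleach_frame is not None
    out: list[DwellRecord] = []
    for ideal in ideals:
        segs = segment_trace(ideal, min_delta, min_dwell)
        dt = ideal.frame_interval
        for i, seg in enumerate(segs):
            last = i == len(segs) - 1
            out.append(DwellRecord(
                trace_id=ideal.trace_id,
                state_class=seg.canonical_class,
                duration=seg.length * dt,
                terminated_by=("transition" if not last else
                               "bleach" if bleached.get(ideal.trace_id, False)
                               else "trace_end"),
                destination_class=(segs[i + 1].canonical_class
                                   if not last else None),
            ))
    return out


def fit_exponential(durations: np.ndarray, frame_interval: float,
                    min_count: int = MIN_DWELLS_FOR_FIT,
                    t_min: float | None = None) -> ExpFit:
    """Nonlinear least squares of the binned dwell histogram.

    Bins are one frame interval wide and start at ``t_min`` (default two
    frames, the filter's floor) so the truncation artifact below the
    minimum detectable dwell never enters the fit.

    Raises ``ValueError`` when fewer than ``min_count`` dwells are
    supplied (callers report the corresponding table entry as absent).
    """
    d = np.asarray(durations, float)
    if len(d) < min_count:
        raise ValueError(f"need >= {min_count} dwells, got {len(d)}")
    dt = frame_interval
    if t_min is None:
        t_min = 2 * dt
    d = d[d >= t_min - 1e-12]
    flags: list[str] = []
    if np.ptp(d) < 1e-12:
        # all dwells identical: tau is unidentifiable
        return ExpFit(0.0, float(len(d)), max(float(d[0]), dt), float("inf"),
                      len(d), ("degenerate",))
    edges = np.arange(t_min, d.max() + 2 * dt, dt)
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    tau0 = max(float(np.mean(d)) - t_min, dt)
    p0 = (0.0, float(counts[0]) if counts[0] > 0 else 1.0, tau0)
    try:
        popt, pcov = curve_fit(
            lambda t, y0, a, tau: y0 + a * np.exp(-t / tau),
            centers, counts, p0=p0,
            bounds=([-np.inf, 0.0, dt / 10.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
        tau_se = float(np.sqrt(pcov[2, 2]))
    except RuntimeError:
        popt = np.asarray(p0)
        tau_se = float("inf")
        flags.append("fit_failed")
    return ExpFit(float(popt[0]), float(popt[1]), float(popt[2]), tau_se,
                  len(d), tuple(flags))


def rate_from_tau(fit: ExpFit) -> float:
    """k = 1/tau."""
    if fit.tau <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 / fit.tau


def estimate_bleach_rate(qc_reports: Iterable[QCReport],
                         frame_interval: float) -> float:
    """Photobleaching rate from pre-bleach trace lengths.

    Maximum-likelihood estimate for exponentially distributed bleach
    times with right-censoring at the observation window: the number of
    observed bleach events divided by the summed pre-bleach observation
    time of all traces.
    """
    n_events = 0
    total_time = 0.0
    for rep in qc_reports:
        total_time += rep.truncated_length * frame_interval
        if rep.bleach_frame is not None:
            n_events += 1
    if n_events == 0:
        raise ValueError("no bleach events observed; rate not estimable")
    return n_events / total_time


def correct_rates(
    k_obs: Mapping[tuple[str, str], float],
    k_bleach: float | Mapping[str, float],
    dead_time: float,
    n_static: int = 0,
    n_dynamic: int = 0,
    t_eff: float = OBSERVATION_TIME,
    static_adjustment: bool = False,
    n_iter: int = 50,
    floor: float = 1e-6,
) -> dict[tuple[str, str], float]:
    """Correct observed branch rates for photobleaching and missed events.

    ``k_obs[(S, D)]`` are the branch-apportioned observed rates. Per
    state, the bleach rate is subtracted from the total observed exit
    rate (competing-risk correction, floored at ``floor`` when bleaching
    dominates); each branch is then divided by the survival probability
    ``p_D = exp(-(k_exit(D) + k_bleach_D) * dead_time)`` of its
    destination's sojourns, iterated to self-consistency. The optional
    static-trace adjustment multiplies every corrected rate by
    ``N_dyn / (N_dyn + N_static * (1 - exp(-k * t_eff)))``.
    """
    if not k_obs:
        return {}
    states = sorted({s for s, _ in k_obs} | {d for _, d in k_obs})

    def kb(state: str) -> float:
        if isinstance(k_bleach, Mapping):
            return float(k_bleach.get(state, 0.0))
        return float(k_bleach)

    exit_obs = {s: sum(v for (a, _), v in k_obs.items() if a == s)
                for s in states}
    frac = {sd: (v / exit_obs[sd[0]] if exit_obs[sd[0]] > 0 else 0.0)
            for sd, v in k_obs.items()}

    k_corr = dict(k_obs)
    for _ in range(n_iter):
        exit_corr = {s: sum(v for (a, _), v in k_corr.items() if a == s)
                     for s in states}
        p = {s: float(np.exp(-(exit_corr[s] + kb(s)) * dead_time))
             for s in states}
        new = {}
        for (s, d2), _ in k_obs.items():
            base = max(exit_obs[s] - kb(s), floor)
            new[(s, d2)] = frac[(s, d2)] * base / p[d2]
        if max(abs(new[sd] - k_corr[sd]) for sd in new) < 1e-12:
            k_corr = new
            break
        k_corr = new

    if static_adjustment and (n_static + n_dynamic) > 0:
        for sd, k in list(k_corr.items()):
            denom = n_dynamic + n_static * (1.0 - np.exp(-k * t_eff))
            k_corr[sd] = k * n_dynamic / denom if denom > 0 else floor
    return k_corr


def estimate_rates(
    ideals: list[IdealizedTrace],
    qc_reports: list[QCReport] | None = None,
    k_bleach: float | None = None,
    min_dwells: int = MIN_DWELLS_FOR_FIT,
    dead_time: float | None = None,
    static_adjustment: bool = False,
    n_static: int = 0,
    n_dynamic: int = 0,
    min_delta: float = MIN_DELTA,
    min_dwell: int = MIN_DWELL_FRAMES,
) -> list[RateEstimate]:
    """Full dwell-time rate analysis of one condition.

    Per state: complete dwells (all destinations pooled) are fitted for
    tau, the exit rate 1/tau is apportioned over destinations by the
    observed transition counts, and :func:`correct_rates` removes the
    photobleaching and dead-time biases. Transitions rarer than
    ``min_dwells`` dwells per source state are reported as absent.
    """
    if not ideals:
        return []
    dt = ideals[0].frame_interval
    if dead_time is None:
        dead_time = 1.5 * dt
    if k_bleach is None:
        k_bleach = (estimate_bleach_rate(qc_reports, dt)
                    if qc_reports else 0.0)
    dwells = extract_dwells(ideals, qc_reports, min_delta, min_dwell)
    complete = [d for d in dwells
                if d.terminated_by == "transition" and d.state_class]

    by_state: dict[str, list[DwellRecord]] = {}
    for d in complete:
        by_state.setdefault(d.state_class, []).append(d)

    k_obs: dict[tuple[str, str], float] = {}
    info: dict[tuple[str, str], tuple[int, ExpFit]] = {}
    for state, recs in by_state.items():
        durations = np.array([r.duration for r in recs])
        try:
            fit = fit_exponential(durations, dt, min_count=min_dwells)
        except ValueError:
            continue
        k_exit = rate_from_tau(fit)
        dest_counts: dict[str, int] = {}
        for r in recs:
            if r.destination_class:
                dest_counts[r.destination_class] = \
                    dest_counts.get(r.destination_class, 0) + 1
        total = sum(dest_counts.values())
        for dest, n in dest_counts.items():
            k_obs[(state, dest)] = k_exit * n / total
            info[(state, dest)] = (n, fit)

    k_corr = correct_rates(k_obs, k_bleach, dead_time,
                           n_static=n_static, n_dynamic=n_dynamic,
                           static_adjustment=static_adjustment)
    out = []
    for (s, d2), k in sorted(k_obs.items()):
        n, fit = info[(s, d2)]
        out.append(RateEstimate(
            from_class=s, to_class=d2, k_obs=float(k),
            k_corr=float(k_corr[(s, d2)]), n_transitions=n,
            k_bleach_state=float(k_bleach), tau_fit=fit,
            flags=fit.flags))
    return out


def back_calculate_reverse_rate(k_forward: float, keq: float) -> float:
    """k_reverse = k_forward / K_eq (detailed balance)."""
    if keq <= 0:
        raise ValueError("K_eq must be > 0")
    return k_forward / keq


def summarize_rate_table(
    condition: str,
    populations: pd.Series,
    rates: list[RateEstimate],
    canonical: CanonicalMap = LT_CANONICAL,
) -> pd.DataFrame:
    """One tidy summary row per adjacent canonical state pair.

    Columns mirror the layout of per-condition rate tables: relative
    populations of the pair, K_eq = P_low / P_high, dG in k_B*T,
    corrected rates in both directions with transition counts, and a
    detailed-balance diagnostic k_f / (k_r * K_eq) (1 at equilibrium).
    """
    from .populations import compute_Keq, compute_deltaG

    k_by_pair = {(r.from_class, r.to_class): r for r in rates}
    present = [c for c in populations.index]
    present.sort(key=canonical.center_of, reverse=True)

    rows = []
    if len(present) == 1:
        rows.append({"condition": condition, "state_high": present[0],
                     "state_low": None, "P_high": populations[present[0]],
                     "P_low": None, "Keq": None, "dG_kBT": None,
                     "k_down": None, "n_down": None, "k_up": None,
                     "n_up": None, "balance": None})
    for high, low in zip(present[:-1], present[1:]):
        p_hi, p_lo = float(populations[high]), float(populations[low])
        keq = compute_Keq(p_hi, p_lo)
        down = k_by_pair.get((high, low))
        up = k_by_pair.get((low, high))
        balance = None
        if down and up and keq:
            balance = down.k_corr / (up.k_corr * keq)
        rows.append({
            "condition": condition,
            "state_high": high, "state_low": low,
            "P_high": p_hi, "P_low": p_lo,
            "Keq": keq,
            "dG_kBT": compute_deltaG(keq) if keq else None,
            "k_down": down.k_corr if down else None,
            "n_down": down.n_transitions if down else None,
            "k_up": up.k_corr if up else None,
            "n_up": up.n_transitions if up else None,
            "balance": balance,
        })
    return pd.DataFrame(rows)
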