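"""Synthetic two-color smFRET trace generation with known ground truth.

Simulates the conformational dynamics of single ribosome complexes as a
continuous-time Markov chain (CTMC) over a small set of FRET states,
renders donor/acceptor photon-count trajectories with camera integration,
donor->acceptor bleed-through, detector noise and single-step
photobleaching, and packages datasets together with a ground-truth sidecar
so that every downstream analysis stage can be validated against truth.

Condition presets encode the experimental situations studied for
tRNA--L11 (Lt) and tRNA--tRNA (tt) FRET pairs: the factor-free PRE and
POST complexes, and PRE complexes engaged by wild-type or mutant EF-G,
which stall distinct chimeric translocation intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticScheme",
    "PhotophysicsParams",
    "AcquisitionParams",
    "ConditionPreset",
    "StatePath",
    "PhotophysicsEvents",
    "GroundTruth",
    "SimulatedDataset",
    "PRESET_NAMES",
    "build_preset",
    "simulate_state_path",
    "apply_photophysics",
    "render_trace",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class KineticScheme:
    """Named FRET states plus the rate matrix connecting them.

    Parameters
    ----------
    state_names
        One label per state, conventionally the nominal FRET class
        (e.g. ``"0.8"``, ``"0.6"``).
    fret_mean
        Mean FRET efficiency of each state, in [0, 1].
    fret_sd
        Per-state emission spread of the FRET coordinate (unitless).
    rate_matrix
        Off-diagonal entries are transition rates in 1/s; the diagonal is
        ignored on input and defined as the negative row sum.
    start_probs
        Optional initial-state distribution. ``None`` means the stationary
        distribution of the chain (suitable for equilibrium conditions);
        transient schemes such as active translocation must set it.
    """

    state_names: tuple[str, ...]
    fret_mean: np.ndarray
    fret_sd: np.ndarray
    rate_matrix: np.ndarray
    start_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "fret_mean", np.asarray(self.fret_mean, float))
        object.__setattr__(self, "fret_sd", np.asarray(self.fret_sd, float))
        object.__setattr__(self, "rate_matrix", np.asarray(self.rate_matrix, float))
        if self.start_probs is not None:
            object.__setattr__(self, "start_probs", np.asarray(self.start_probs, float))
        k = self.n_states
        if self.fret_mean.shape != (k,) or self.fret_sd.shape != (k,):
            raise ValueError("fret_mean/fret_sd must have one entry per state")
        if self.rate_matrix.shape != (k, k):
            raise ValueError("rate_matrix must be square with one row per state")
        off = self.rate_matrix[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if k > 1:
            gaps = np.abs(np.subtract.outer(self.fret_mean, self.fret_mean))
            if np.min(gaps[~np.eye(k, dtype=bool)]) < 0.05:
                raise ValueError("state FRET means must be distinct by >= 0.05")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def generator(self) -> np.ndarray:
        """Infinitesimal generator Q: off-diagonal rates, diagonal = -row sum."""
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution pi solving pi Q = 0, sum(pi) = 1.

        For reducible chains this returns the distribution supported on the
        recurrent states (least-squares solution of the augmented system).
        """
        q = self.generator()
        k = self.n_states
        a = np.vstack([q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def initial_distribution(self) -> np.ndarray:
        if self.start_probs is not None:
            p = np.clip(self.start_probs, 0.0, None)
            return p / p.sum()
        return self.stationary_distribution()

    def index_of(self, name: str) -> int:
        return self.state_names.index(name)


@dataclass(frozen=True)
class PhotophysicsParams:
    """Fluorophore photophysics of the simulated dye pair.

    Default bleach rates of 0.05 1/s per dye give a combined 0.1 1/s,
    i.e. a mean analyzable trace length of ~10 s. Bleed-through beta is
    the fraction of donor signal leaking into the acceptor channel.
    Blinking is off by default.
    """

    bleach_rate_donor: float = 0.05
    bleach_rate_acceptor: float = 0.05
    blink_on_rate: float = 0.0
    blink_off_rate: float = 0.0
    bleedthrough: float = 0.13
    noise_sd: float = 60.0
    brightness: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bleedthrough < 1.0):
            raise ValueError("bleedthrough must be in [0, 1)")
        for r in (self.bleach_rate_donor, self.bleach_rate_acceptor,
                  self.blink_on_rate, self.blink_off_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.brightness <= 0:
            raise ValueError("brightness must be > 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera timing: 30 frames per second by default, 33 s observation."""

    frame_interval: float = 0.033
    observation_window: float = 33.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.observation_window < self.frame_interval:
            raise ValueError("observation_window must cover >= 1 frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.observation_window / self.frame_interval))


@dataclass(frozen=True)
class ConditionPreset:
    """A fully parameterized experimental condition."""

    name: str
    scheme: KineticScheme
    static_fraction: float = 0.0
    forbidden_transitions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.static_fraction <= 1.0):
            raise ValueError("static_fraction must be in [0, 1]")
        for a, b in self.forbidden_transitions:
            if a not in self.scheme.state_names or b not in self.scheme.state_names:
                raise ValueError(f"forbidden transition ({a}, {b}) names unknown state")


# ---------------------------------------------------------------------------
# condition presets
#
# Emission means/SDs follow the published state parameters of the Lt-FRET
# (L11--tRNA) pair: 0.76+/-0.12 (FRET 0.8, classical PRE), 0.56+/-0.08
# (FRET 0.6, hybrid PRE), 0.40+/-0.09 (chimeric intermediate), 0.24+/-0.11
# (POST); and of the tt-FRET pair: 0.73+/-0.13, 0.46+/-0.12, 0.85+/-0.12.
# Transition rates are the per-condition corrected rates (1/s).

_LT = {
    "0.8": (0.76, 0.12),
    "0.6": (0.56, 0.08),
    "0.4": (0.40, 0.09),
    "0.2": (0.24, 0.11),
}
_TT = {
    "0.7": (0.73, 0.13),
    "0.5": (0.46, 0.12),
    "0.9": (0.85, 0.12),
}


def _scheme(levels: Mapping[str, tuple[float, float]],
            names: Sequence[str],
            rates: Mapping[tuple[str, str], float],
            start: str | Mapping[str, float] | None = None) -> KineticScheme:
    names = list(names)
    k = len(names)
    q = np.zeros((k, k))
    for (a, b), r in rates.items():
        q[names.index(a), names.index(b)] = r
    start_probs = None
    if isinstance(start, str):
        start_probs = np.zeros(k)
        start_probs[names.index(start)] = 1.0
    elif isinstance(start, Mapping):
        start_probs = np.array([start.get(n, 0.0) for n in names])
    return KineticScheme(
        state_names=tuple(names),
        fret_mean=np.array([levels[n][0] for n in names]),
        fret_sd=np.array([levels[n][1] for n in names]),
        rate_matrix=q,
        start_probs=start_probs,
    )


def _build_presets() -> dict[str, ConditionPreset]:
    p: dict[str, ConditionPreset] = {}

    # Factor-free PRE: C <-> H exchange, about half of the complexes static.
    # Exchange rates are not tabulated for the factor-free complex; 3 /s each
    # way reproduces the observed roughly equal C/H occupancy and lies in the
    # 1-8 /s range typical of all measured transitions.
    p["PRE"] = ConditionPreset(
        name="PRE",
        scheme=_scheme(_LT, ["0.8", "0.6"], {("0.8", "0.6"): 3.0, ("0.6", "0.8"): 3.0}),
        static_fraction=0.5,
    )
    # POST complex: static single state at FRET 0.24.
    p["POST"] = ConditionPreset(
        name="POST",
        scheme=_scheme(_LT, ["0.2"], {}),
        static_fraction=1.0,
    )
    # Active translocation with wt EF-G + GTP: PRE states decay to POST
    # within about one frame (>= 30 /s), no return to high FRET.
    p["EFG_wt"] = ConditionPreset(
        name="EFG_wt",
        scheme=_scheme(
            _LT, ["0.8", "0.6", "0.2"],
            {("0.8", "0.6"): 3.0, ("0.6", "0.8"): 3.0,
             ("0.8", "0.2"): 30.0, ("0.6", "0.2"): 30.0},
            start={"0.8": 0.5, "0.6": 0.5},
        ),
        forbidden_transitions=(("0.2", "0.6"), ("0.2", "0.8")),
    )
    # EF-G(XL), cross-link intact: stable 0.6 <-> 0.4 fluctuations.
    p["XL"] = ConditionPreset(
        name="XL",
        scheme=_scheme(
            _LT, ["0.6", "0.4"],
            {("0.6", "0.4"): 7.9, ("0.4", "0.6"): 1.2},
            start="0.6",
        ),
    )
    # wt EF-G with GTPgammaS: 0.6/0.4 exchange plus slow leak to 0.2.
    p["wt_GTPgS"] = ConditionPreset(
        name="wt_GTPgS",
        scheme=_scheme(
            _LT, ["0.6", "0.4", "0.2"],
            {("0.6", "0.4"): 6.9, ("0.4", "0.6"): 0.5,
             ("0.4", "0.2"): 0.8, ("0.2", "0.4"): 4.2},
            start="0.6",
        ),
        forbidden_transitions=(("0.2", "0.6"), ("0.6", "0.2")),
    )
    # EF-G lacking domains 4/5: all three chimeric states interconvert.
    p["D45"] = ConditionPreset(
        name="D45",
        scheme=_scheme(
            _LT, ["0.6", "0.4", "0.2"],
            {("0.6", "0.4"): 6.0, ("0.4", "0.6"): 3.0,
             ("0.4", "0.2"): 2.9, ("0.2", "0.4"): 7.6,
             ("0.6", "0.2"): 3.7, ("0.2", "0.6"): 6.2},
            start="0.6",
        ),
    )
    p["H91A"] = ConditionPreset(
        name="H91A",
        scheme=_scheme(
            _LT, ["0.6", "0.4", "0.2"],
            {("0.6", "0.4"): 7.2, ("0.4", "0.6"): 4.2,
             ("0.4", "0.2"): 3.9, ("0.2", "0.4"): 7.2,
             ("0.6", "0.2"): 4.8, ("0.2", "0.6"): 7.0},
            start="0.6",
        ),
    )
    p["H583K"] = ConditionPreset(
        name="H583K",
        scheme=_scheme(
            _LT, ["0.6", "0.4", "0.2"],
            {("0.6", "0.4"): 7.1, ("0.4", "0.6"): 4.7,
             ("0.4", "0.2"): 4.7, ("0.2", "0.4"): 7.9,
             ("0.6", "0.2"): 3.2, ("0.2", "0.6"): 5.9},
            start="0.6",
        ),
    )
    # wt EF-G stalled with fusidic acid: 0.4 <-> 0.2 exchange.
    p["wt_Fus"] = ConditionPreset(
        name="wt_Fus",
        scheme=_scheme(
            _LT, ["0.4", "0.2"],
            {("0.4", "0.2"): 3.8, ("0.2", "0.4"): 4.3},
            start="0.4",
        ),
    )
    # tRNA--tRNA FRET pair, factor-free PRE: 0.73/0.46 exchange.
    p["ttPRE"] = ConditionPreset(
        name="ttPRE",
        scheme=_scheme(_TT, ["0.7", "0.5"], {("0.7", "0.5"): 3.0, ("0.5", "0.7"): 3.0}),
        static_fraction=0.5,
    )
    # tRNA--tRNA FRET pair stalled by fusidic acid: static 0.85 state.
    p["ttFus"] = ConditionPreset(
        name="ttFus",
        scheme=_scheme(_TT, ["0.9"], {}),
        static_fraction=1.0,
    )
    return p


_PRESETS = _build_presets()
PRESET_NAMES = tuple(_PRESETS.keys())


def build_preset(name: str) -> ConditionPreset:
    """Return the fully parameterized preset for a named condition.

    Raises
    ------
    KeyError
        If ``name`` is not a known condition; the message lists valid names.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class StatePath:
    """Continuous-time trajectory: state index and entry time per sojourn."""

    states: np.ndarray
    entry_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        if len(self.states) != len(self.entry_times):
            raise ValueError("states and entry_times must align")

    @property
    def exit_times(self) -> np.ndarray:
        return np.append(self.entry_times[1:], self.duration)

    def sojourn_durations(self) -> np.ndarray:
        return self.exit_times - self.entry_times


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    start_state: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> StatePath:
    """Gillespie simulation of the CTMC defined by ``scheme``.

    Sojourn times are exponential with the state's total exit rate; the
    destination is drawn proportionally to the individual rates. A state
    with no exits (absorbing, or a deliberately frozen scheme) yields a
    single sojourn spanning the full duration.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(rng)
    q = scheme.rate_matrix.copy()
    np.fill_diagonal(q, 0.0)
    exit_rates = q.sum(axis=1)

    if start_state is None:
        state = int(rng.choice(scheme.n_states, p=scheme.initial_distribution()))
    else:
        state = int(start_state)

    states = [state]
    times = [0.0]
    t = 0.0
    while True:
        k_out = exit_rates[state]
        if k_out <= 0.0:
            break
        t += rng.exponential(1.0 / k_out)
        if t >= duration:
            break
        state = int(rng.choice(scheme.n_states, p=q[state] / k_out))
        states.append(state)
        times.append(t)
    return StatePath(np.array(states, int), np.array(times, float), duration)


@dataclass(frozen=True)
class PhotophysicsEvents:
    """Bleach times (None if beyond the observation window) and blink spans."""

    donor_bleach_time: float | None
    acceptor_bleach_time: float | None
    blink_intervals: tuple[tuple[float, float], ...] = ()


def apply_photophysics(
    params: PhotophysicsParams,
    duration: float,
    rng: np.random.Generator | int | None = None,
) -> PhotophysicsEvents:
    """Draw exponential bleach times and (optional) donor blink intervals."""
    rng = np.random.default_rng(rng)

    def _bleach(rate: float) -> float | None:
        if rate <= 0:
            return None
        t = rng.exponential(1.0 / rate)
        return t if t < duration else None

    donor = _bleach(params.bleach_rate_donor)
    acceptor = _bleach(params.bleach_rate_acceptor)

    blinks: list[tuple[float, float]] = []
    if params.blink_off_rate > 0 and params.blink_on_rate > 0:
        end = duration if donor is None else donor
        t = 0.0
        while True:
            t += rng.exponential(1.0 / params.blink_off_rate)
            if t >= end:
                break
            dark = rng.exponential(1.0 / params.blink_on_rate)
            blinks.append((t, min(t + dark, end)))
            t += dark
            if t >= end:
                break
    return PhotophysicsEvents(donor, acceptor, tuple(blinks))


@dataclass
class GroundTruth:
    """Per-trace truth record written alongside each simulated trace."""

    trace_id: str
    true_state_path: np.ndarray
    bleach_frame_donor: int | None
    bleach_frame_acceptor: int | None
    is_static: bool
    true_rates: np.ndarray
    true_fret: np.ndarray


def _frame_occupancy(path: StatePath, n_frames: int, dt: float, n_states: int
                     ) -> np.ndarray:
    """Fraction of each frame spent in each state, shape (n_frames, K).

    Uses the piecewise-linear cumulative occupancy of each state evaluated
    at the frame boundaries, so mid-frame transitions are weighted exactly.
    """
    bounds = np.arange(n_frames + 1) * dt
    knots = np.append(path.entry_times, path.duration)
    occ = np.empty((n_frames, n_states))
    for s in range(n_states):
        seg = (path.states == s).astype(float)
        cum = np.concatenate([[0.0], np.cumsum(seg * path.sojourn_durations())])
        at_bounds = np.interp(bounds, knots, cum)
        occ[:, s] = np.diff(at_bounds) / dt
    return occ


def render_trace(
    path: StatePath,
    events: PhotophysicsEvents,
    scheme: KineticScheme,
    photophysics: PhotophysicsParams,
    acquisition: AcquisitionParams,
    rng: np.random.Generator | int | None = None,
    trace_id: str = "trace",
    is_static: bool = False,
):
    """Render a CTMC path into per-frame donor/acceptor count series.

    Per frame, the underlying FRET coordinate is the occupancy-weighted
    mean of the occupied states' FRET means plus a Gaussian emission
    jitter with the occupancy-weighted state SD (modelling the dye-pair
    fluctuations that dominate the observed FRET spread). Channels:

        donor    = brightness * (1 - E) + detector noise
        acceptor = brightness * E + beta * donor_signal + detector noise

    After acceptor bleach the acceptor signal drops to background and the
    donor de-quenches to full brightness; after donor bleach (or during a
    donor blink) both channels fall to background. Mid-frame photophysics
    events are weighted by the fraction of the frame before the event.

    Returns a ``(RawTrace, GroundTruth)`` pair.
    """
    from .trace_qc import RawTrace  # local import to avoid a cycle

    rng = np.random.default_rng(rng)
    dt = acquisition.frame_interval
    n = acquisition.n_frames
    occ = _frame_occupancy(path, n, dt, scheme.n_states)
    e_true = occ @ scheme.fret_mean
    sd_eff = occ @ scheme.fret_sd
    e_obs = e_true + rng.standard_normal(n) * sd_eff

    bounds = np.arange(n + 1) * dt

    def _alive_fraction(t_event: float | None) -> np.ndarray:
        if t_event is None:
            return np.ones(n)
        return np.clip((t_event - bounds[:-1]) / dt, 0.0, 1.0)

    donor_alive = _alive_fraction(events.donor_bleach_time)
    for t0, t1 in events.blink_intervals:
        dark = np.clip((np.minimum(bounds[1:], t1) - np.maximum(bounds[:-1], t0)) / dt,
                       0.0, 1.0)
        donor_alive = donor_alive * (1.0 - dark)
    acc_alive = _alive_fraction(events.acceptor_bleach_time)

    s = photophysics.brightness
    # while both dyes are alive: donor quenched by FRET; acceptor emits E
    d_signal = s * donor_alive * (acc_alive * (1.0 - e_obs) + (1.0 - acc_alive))
    a_signal = s * donor_alive * acc_alive * e_obs

    noise = photophysics.noise_sd
    donor_counts = d_signal + rng.standard_normal(n) * noise
    acceptor_counts = (a_signal + photophysics.bleedthrough * d_signal
                       + rng.standard_normal(n) * noise)

    def _frame_of(t_event: float | None) -> int | None:
        if t_event is None:
            return None
        return min(int(t_event / dt), n - 1)

    truth = GroundTruth(
        trace_id=trace_id,
        true_state_path=np.argmax(occ, axis=1),
        bleach_frame_donor=_frame_of(events.donor_bleach_time),
        bleach_frame_acceptor=_frame_of(events.acceptor_bleach_time),
        is_static=is_static,
        true_rates=scheme.rate_matrix.copy(),
        true_fret=e_true,
    )
    raw = RawTrace(trace_id=trace_id, donor=donor_counts, acceptor=acceptor_counts,
                   frame_interval=dt)
    return raw, truth


@dataclass
class SimulatedDataset:
    """Trace table, ground-truth sidecars and the generation manifest."""

    traces: pd.DataFrame
    truth_frames: pd.DataFrame
    truth_traces: pd.DataFrame
    manifest: dict
    scheme: KineticScheme

    def raw_traces(self) -> list:
        from .trace_qc import RawTrace

        dt = self.manifest["acquisition"]["frame_interval"]
        out = []
        for tid, g in self.traces.groupby("trace_id", sort=False):
            out.append(RawTrace(trace_id=str(tid),
                                donor=g["donor"].to_numpy(float),
                                acceptor=g["acceptor"].to_numpy(float),
                                frame_interval=dt))
        return out

    def save(self, outdir) -> None:
        from . import io as _io

        _io.save_dataset(self, outdir)


def generate_dataset(
    preset: ConditionPreset | str,
    n_traces: int,
    seed: int,
    photophysics: PhotophysicsParams | None = None,
    acquisition: AcquisitionParams | None = None,
    static_fraction: float | None = None,
) -> SimulatedDataset:
    """Generate an independent set of traces for one condition.

    Each trace is drawn static with probability ``static_fraction`` (from
    the preset unless overridden): a static trace is frozen in a state
    sampled from the scheme's initial distribution, a dynamic trace follows
    the CTMC. Deterministic for a fixed seed.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if isinstance(preset, str):
        preset = build_preset(preset)
    photophysics = photophysics or PhotophysicsParams()
    acquisition = acquisition or AcquisitionParams()
    p_static = preset.static_fraction if static_fraction is None else static_fraction

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traces)
    t_rows, f_rows, tr_rows = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        tid = f"{preset.name}_{i:05d}"
        is_static = bool(rng.random() < p_static)
        duration = acquisition.observation_window
        if is_static:
            state = int(rng.choice(preset.scheme.n_states,
                                   p=preset.scheme.initial_distribution()))
            path = StatePath(np.array([state]), np.array([0.0]), duration)
        else:
            path = simulate_state_path(preset.scheme, duration, rng=rng)
        events = apply_photophysics(photophysics, duration, rng=rng)
        raw, truth = render_trace(path, events, preset.scheme, photophysics,
                                  acquisition, rng=rng, trace_id=tid,
                                  is_static=is_static)
        n = len(raw.donor)
        t_rows.append(pd.DataFrame({
            "trace_id": tid,
            "frame": np.arange(n),
            "donor": raw.donor,
            "acceptor": raw.acceptor,
        }))
        f_rows.append(pd.DataFrame({
            "trace_id": tid,
            "frame": np.arange(n),
            "state_index": truth.true_state_path,
            "state_label": [preset.scheme.state_names[s]
                            for s in truth.true_state_path],
            "true_fret": truth.true_fret,
        }))
        tr_rows.append({
            "trace_id": tid,
            "is_static": is_static,
            "bleach_frame_donor": truth.bleach_frame_donor,
            "bleach_frame_acceptor": truth.bleach_frame_acceptor,
        })

    manifest = {
        "preset": preset.name,
        "seed": int(seed),
        "n_traces": int(n_traces),
        "static_fraction": float(p_static),
        "photophysics": asdict(photophysics),
        "acquisition": asdict(acquisition),
        "scheme": {
            "state_names": list(preset.scheme.state_names),
            "fret_mean": preset.scheme.fret_mean.tolist(),
            "fret_sd": preset.scheme.fret_sd.tolist(),
            "rate_matrix": preset.scheme.rate_matrix.tolist(),
        },
    }
    return SimulatedDataset(
        traces=pd.concat(t_rows, ignore_index=True),
        truth_frames=pd.concat(f_rows, ignore_index=True),
        truth_traces=pd.DataFrame(tr_rows),
        manifest=manifest,
        scheme=preset.scheme,
    )
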