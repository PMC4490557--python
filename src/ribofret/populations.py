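"""State populations, FRET histograms, contour matrices and energetics.

Histograms span [-0.1, 1.1] in 0.025-wide bins so that noise excursions
outside the physical FRET range are retained. Population fractions P are
frame-occupancy fractions of the canonical classes; for translocation
experiments they are evaluated over the first 45 frames (1.5 s) after
post-synchronization. Equilibrium constants follow K_eq = P_S2 / P_S1 and
free-energy differences dG = -ln(K_eq) in units of k_B*T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, nnls
from scipy.special import erf

from .idealization import IdealizedTrace
from .trace_qc import FRETTrace
from .transitions import SyncedTrace

__all__ = [
    "FRETHistogram",
    "GaussianComponent",
    "default_bin_edges",
    "build_histogram",
    "build_contour",
    "fit_gaussian_mixture",
    "compute_populations",
    "compute_Keq",
    "compute_deltaG",
]

HIST_RANGE = (-0.1, 1.1)
BIN_WIDTH = 0.025
SYNC_WINDOW_FRAMES = 45


def default_bin_edges(width: float = BIN_WIDTH) -> np.ndarray:
    lo, hi = HIST_RANGE
    return np.arange(lo, hi + width / 2, width)


@dataclass
class FRETHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float     # component mass in counts
    flagged: bool = False


def _pooled_values(traces, window: int | None) -> np.ndarray:
    vals = []
    for t in traces:
        if isinstance(t, SyncedTrace):
            if t.efficiency is None:
                raise ValueError("synced trace lacks an efficiency series")
            sel = t.aligned_frames >= 0
            if window is not None:
                sel &= t.aligned_frames < window
            vals.append(t.efficiency[sel])
        else:
            e = t.efficiency if isinstance(t, FRETTrace) else np.asarray(t, float)
            vals.append(e if window is None else e[:window])
    if not vals:
        return np.empty(0)
    pooled = np.concatenate(vals)
    return pooled[np.isfinite(pooled)]


def build_histogram(traces, bins: np.ndarray | None = None,
                    window: int | None = SYNC_WINDOW_FRAMES) -> FRETHistogram:
    """Pool frames of many traces into a 1-D FRET histogram.

    For :class:`SyncedTrace` inputs only aligned frames 0 .. window-1 are
    pooled; for plain FRET traces the first ``window`` frames (or all
    frames when ``window`` is None). Frames beyond a trace's truncation
    point never reach this function: truncation happened during QC.
    """
    edges = default_bin_edges() if bins is None else np.asarray(bins, float)
    counts, _ = np.histogram(_pooled_values(traces, window), bins=edges)
    return FRETHistogram(edges, counts.astype(float))


def build_contour(synced: list[SyncedTrace],
                  bins: np.ndarray | None = None,
                  window: int = SYNC_WINDOW_FRAMES,
                  pre_frames: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-resolved (aligned frame x FRET bin) count matrix.

    Returns ``(matrix, frame_axis, bin_edges)`` where the frame axis runs
    from ``-pre_frames`` to ``window - 1`` relative to the sync point.
    """
    edges = default_bin_edges() if bins is None else np.asarray(bins, float)
    frames = np.arange(-pre_frames, window)
    mat = np.zeros((len(frames), len(edges) - 1))
    for t in synced:
        if t.efficiency is None:
            continue
        for row, f in enumerate(frames):
            idx = np.flatnonzero(t.aligned_frames == f)
            if idx.size:
                v = t.efficiency[idx[0]]
                if np.isfinite(v):
                    b = np.searchsorted(edges, v, side="right") - 1
                    if 0 <= b < mat.shape[1]:
                        mat[row, b] += 1
    return mat, frames, edges


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sd = params[i:i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def fit_gaussian_mixture(hist: FRETHistogram, n_components: int,
                         init_means: np.ndarray | None = None,
                         init_sd: float = 0.1,
                         sd_floor: float = 0.02,
                         ) -> tuple[list[GaussianComponent], float]:
    """Unweighted least-squares fit of the binned counts to a Gaussian sum.

    Components are initialized at ``init_means`` (default: evenly spaced
    quantile positions of the histogram mass) with SD 0.1 and equal
    amplitudes. A component collapsing below ``sd_floor`` triggers one
    refit with its SD pinned to the floor and is flagged. Returns the
    components sorted by mean and the residual norm.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if hist.total <= 0:
        raise ValueError("histogram is empty")
    x = hist.centers
    y = hist.counts
    if init_means is None:
        cdf = np.cumsum(y) / y.sum()
        q = (np.arange(n_components) + 0.5) / n_components
        init_means = np.interp(q, cdf, x)
    amp0 = y.max() / n_components
    p0, lo, hi = [], [], []
    width = x[-1] - x[0]
    for m in np.sort(np.asarray(init_means, float)):
        p0 += [amp0, m, init_sd]
        lo += [0.0, x[0] - 0.1, 1e-4]
        hi += [np.inf, x[-1] + 0.1, width]
    try:
        popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
    except RuntimeError:
        popt = np.asarray(p0)

    flagged = False
    if np.any(popt[2::3] < sd_floor):
        flagged = True
        lo2 = list(lo)
        for i in range(2, len(lo2), 3):
            lo2[i] = sd_floor
        try:
            popt, _ = curve_fit(_gauss_sum, x, y, p0=np.maximum(popt, lo2),
                                bounds=(lo2, hi), maxfev=20000)
        except RuntimeError:
            pass

    resid = float(np.linalg.norm(y - _gauss_sum(x, *popt)))
    bw = float(np.mean(np.diff(hist.bin_edges)))
    comps = []
    for i in range(0, len(popt), 3):
        a, mu, sd = popt[i:i + 3]
        weight = a * sd * np.sqrt(2 * np.pi) / bw   # mass in counts
        comps.append(GaussianComponent(float(mu), float(sd), float(weight),
                                       flagged))
    comps.sort(key=lambda c: c.mean)
    return comps, resid


def compute_populations(
    ideals: list[IdealizedTrace],
    window: int | None = None,
    sync_frames: dict[str, int] | None = None,
) -> pd.Series:
    """Relative population P of each canonical class by frame occupancy.

    Pools dynamic and static traces. When ``sync_frames`` is given, only
    the ``window`` frames following each trace's sync point are counted
    (traces without a sync point are skipped); otherwise the first
    ``window`` frames of every trace (all frames when None). Frames are
    attributed per the filtered dwell sequence, so transition-blur frames
    count toward the dwell that absorbed them; unassigned frames are
    excluded from the denominator. The result sums to 1.
    """
    from .transitions import segment_trace

    counts: dict[str, int] = {}
    for ideal in ideals:
        n = len(ideal)
        if sync_frames is not None:
            if ideal.trace_id not in sync_frames:
                continue
            start = sync_frames[ideal.trace_id]
        else:
            start = 0
        stop = n if window is None else min(n, start + window)
        for seg in segment_trace(ideal):
            overlap = min(seg.end, stop) - max(seg.start, start)
            if overlap > 0 and seg.canonical_class is not None:
                counts[seg.canonical_class] = \
                    counts.get(seg.canonical_class, 0) + overlap
    total = sum(counts.values())
    if total == 0:
        return pd.Series(dtype=float)
    s = pd.Series({k: v / total for k, v in counts.items()})
    return s.sort_index(ascending=False)


def effective_smoothed_sd(mean: float, raw_sd: float,
                          noise_sd: float = 60.0, brightness: float = 1000.0,
                          bleedthrough: float = 0.13,
                          smooth_window: int = 3) -> float:
    """Spread of a state's smoothed FRET signal given the detector model."""
    ch = (noise_sd / brightness
          * np.sqrt((1 - mean) ** 2 * (1 + bleedthrough ** 2) + mean ** 2))
    return float(np.sqrt((raw_sd ** 2 + ch ** 2) / smooth_window))


def unmix_populations(hist: FRETHistogram,
                      states: dict[str, tuple[float, float]],
                      include_bridges: bool = True) -> pd.Series:
    """Histogram unmixing with known state emission parameters.

    Solves a nonnegative linear least-squares problem whose basis is one
    Gaussian per state (mean and *effective smoothed* SD supplied by the
    caller) plus, optionally, one "bridge" per adjacent state pair: the
    density of camera-mixed transition frames, a uniform mixture of the
    two levels convolved with the noise (a difference of error
    functions). Bridge mass is attributed half to each endpoint state,
    which is exact in expectation for uniform mixing. Unlike
    frame-occupancy counting this does not rely on idealizing frames
    that are mid-transition, so it stays unbiased when a large fraction
    of frames is transition-blurred.
    """
    x = hist.centers
    labels = sorted(states, key=lambda c: states[c][0], reverse=True)
    cols = []
    for lab in labels:
        m, s = states[lab]
        cols.append(np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi)))
    pairs = list(zip(labels[:-1], labels[1:])) if include_bridges else []
    for a, b in pairs:
        (m1, s1), (m2, s2) = states[a], states[b]
        lo, hi = min(m1, m2), max(m1, m2)
        sb = 0.5 * (s1 + s2)
        cols.append((erf((x - lo) / (sb * np.sqrt(2)))
                     - erf((x - hi) / (sb * np.sqrt(2)))) / (2 * (hi - lo)))
    total = hist.counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    w, _ = nnls(np.column_stack(cols), hist.counts / total)
    occ = {lab: w[i] for i, lab in enumerate(labels)}
    for p, (a, b) in enumerate(pairs):
        occ[a] += 0.5 * w[len(labels) + p]
        occ[b] += 0.5 * w[len(labels) + p]
    z = sum(occ.values())
    return pd.Series({lab: v / z for lab, v in occ.items()}).sort_index(
        ascending=False)


def compute_Keq(p_s1: float, p_s2: float) -> float | None:
    """Equilibrium constant K_eq = P_S2 / P_S1 (None when P_S1 is zero)."""
    if p_s1 < 0 or p_s2 < 0:
        raise ValueError("populations must be >= 0")
    if p_s1 == 0:
        return None
    return p_s2 / p_s1


def compute_deltaG(keq: float) -> float:
    """Free-energy difference dG = -ln(K_eq) in k_B*T units.

    Negative values mean the forward (S2) state is favored.
    """
    if keq <= 0:
        raise ValueError("K_eq must be > 0")
    return float(-np.log(keq))
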