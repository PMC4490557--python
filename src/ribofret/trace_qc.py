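"""Raw-trace quality control: bleed-through correction, bleach detection,
trace selection, truncation, smoothing and FRET calculation.

The chain applied by :func:`select_and_truncate` is:

1. subtract donor bleed-through from the acceptor channel,
2. detect photobleach/blink steps and truncate at the first one,
3. reject traces with a donor or acceptor lifetime below 10 frames or with
   multiple bleach steps in one channel,
4. require anti-correlated donor/acceptor fluctuations,
5. smooth both channels over three data points,
6. convert to FRET efficiency E = acceptor / (donor + acceptor).

Truncation deliberately precedes smoothing so the bleach step is not
smeared into the analyzed window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "RawTrace",
    "FRETTrace",
    "QCReport",
    "QCRules",
    "correct_bleedthrough",
    "smooth",
    "detect_bleach_steps",
    "check_anticorrelation",
    "compute_fret",
    "select_and_truncate",
]

RejectionReason = Literal[
    "short_lifetime", "multi_step_bleach", "not_anticorrelated", "other"
]


@dataclass(frozen=True)
class RawTrace:
    """Per-frame donor (Cy3) and acceptor (Cy5) intensities of one molecule."""

    trace_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "donor", np.asarray(self.donor, float))
        object.__setattr__(self, "acceptor", np.asarray(self.acceptor, float))
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D series of equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.donor)


@dataclass(frozen=True)
class FRETTrace:
    """FRET efficiency trajectory of an accepted, truncated trace."""

    trace_id: str
    efficiency: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "efficiency", np.asarray(self.efficiency, float))

    def __len__(self) -> int:
        return len(self.efficiency)


@dataclass(frozen=True)
class QCReport:
    trace_id: str
    accepted: bool
    rejection_reason: RejectionReason | None
    bleach_frame: int | None
    truncated_length: int
    anticorrelation: float | None = None


@dataclass(frozen=True)
class QCRules:
    """Selection thresholds; defaults follow the published analysis."""

    beta: float = 0.13
    min_lifetime: int = 10          # frames (0.33 s at 30 fps)
    max_bleach_steps: int = 1       # per channel
    anticorrelation_threshold: float | None = -0.3  # None disables the check
    smooth_window: int = 3
    max_invalid_fraction: float = 0.05
    step_window: int = 5            # frames per side for the step statistic
    step_nsd: float = 4.0           # step size threshold in local SDs
    background_run: int = 5         # frames that must stay at background


def correct_bleedthrough(trace: RawTrace, beta: float = 0.13) -> RawTrace:
    """Remove the donor->acceptor spectral bleed-through.

    acceptor' = acceptor - beta * donor, donor unchanged.
    """
    if not (0.0 <= beta < 1.0):
        raise ValueError("beta must be in [0, 1)")
    return replace(trace, acceptor=trace.acceptor - beta * trace.donor)


def smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; the window shrinks at the series edges.

    With the default three-point window the first and last points are
    averaged over two points only, so no values are extrapolated and the
    series length is preserved.
    """
    values = np.asarray(values, float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(values):
        raise ValueError("window larger than trace")
    if window == 1:
        return values.copy()
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def _noise_floor(x: np.ndarray, w: int = 50) -> float:
    """Detector-noise estimate: smallest windowed difference-based SD.

    Post-bleach background carries only detector noise, so the minimum
    over windows is a good noise-floor estimate whenever a background
    segment exists; during pure signal it is an upper bound, which only
    makes the step test more permissive (candidates are re-checked
    against the background level anyway). Windows of 50 diffs keep the
    minimum-of-medians from undershooting the true SD.
    """
    n = len(x)
    if n < 2:
        return 0.0
    d = np.abs(np.diff(x))
    sds = [np.median(d[i:i + w]) for i in range(0, max(len(d) - w + 1, 1), w)]
    return float(min(sds)) * 1.4826 / np.sqrt(2)


def _channel_steps(x: np.ndarray, total: np.ndarray, w: int, nsd: float,
                   run: int) -> list[int]:
    """Downward intensity steps in one channel.

    A candidate at frame t is a drop of the ``w``-frame mean exceeding
    ``nsd`` standard errors of the noise floor. A candidate is reported
    as a step when either (a) the channel then sits at background (pure
    photobleach: mean over the next ``run`` frames within 3 noise-floor
    SDs of zero), or (b) the drop amplitude exceeds 80% of the remaining
    total intensity (a partial bleach step of a multi-fluorophore spot,
    which no single FRET transition can produce).
    """
    n = len(x)
    if n < 2 * w:
        return []
    csum = np.concatenate([[0.0], np.cumsum(x)])
    pre = (csum[w:n - w + 1] - csum[:n - 2 * w + 1]) / w       # mean x[t-w:t]
    post = (csum[2 * w:n + 1] - csum[w:n - w + 1]) / w         # mean x[t:t+w]
    ts = np.arange(w, n - w + 1)
    floor = _noise_floor(x)
    sd_stat = max(floor / np.sqrt(w), 1e-12)   # SE of the post-window mean

    drop = pre - post
    cand = drop > nsd * sd_stat
    steps: list[int] = []
    i = 0
    while i < len(ts):
        if not cand[i]:
            i += 1
            continue
        j = i
        while j < len(ts) and cand[j]:
            j += 1
        best = i + int(np.argmax(drop[i:j]))   # sharpest point of this stretch
        t = int(ts[best])
        tail = x[t + 1:t + 1 + run]            # skip the (possibly partial) step frame
        at_background = (len(tail) > 0 and
                         abs(float(np.mean(tail)))
                         <= max(3.0 * floor / np.sqrt(run), 1e-9))
        partial = drop[best] > 0.8 * max(float(np.mean(total[t:t + w])), 1e-12)
        if at_background or partial:
            steps.append(t)
        if at_background:
            break          # channel is dead; later "steps" are noise
        i = j
    return steps


def detect_bleach_steps(trace: RawTrace, rules: QCRules | None = None
                        ) -> list[tuple[str, int]]:
    """Locate photobleach (and partial-bleach) steps in each channel.

    Expects the bleed-through-corrected trace so that after acceptor
    photobleach the acceptor channel falls to background rather than to
    the bleed-through level. Returns ``(channel, frame)`` pairs ordered
    by frame.
    """
    rules = rules or QCRules()
    w, nsd, run = rules.step_window, rules.step_nsd, rules.background_run
    total = trace.donor + trace.acceptor
    steps = [("donor", f)
             for f in _channel_steps(trace.donor, total, w, nsd, run)]
    steps += [("acceptor", f)
              for f in _channel_steps(trace.acceptor, total, w, nsd, run)]
    return sorted(steps, key=lambda s: s[1])


def check_anticorrelation(trace: RawTrace, window: int | None = None) -> float:
    """Pearson correlation of donor vs acceptor over the pre-bleach window.

    Returns NaN when either channel is constant (statistic undefined).
    """
    end = len(trace) if window is None else min(window, len(trace))
    d = trace.donor[:end]
    a = trace.acceptor[:end]
    if np.std(d) == 0.0 or np.std(a) == 0.0:
        return float("nan")
    return float(np.corrcoef(d, a)[0, 1])


def compute_fret(trace: RawTrace, max_invalid_fraction: float = 0.05
                 ) -> FRETTrace | None:
    """E_t = acceptor_t / (donor_t + acceptor_t) per frame.

    Frames with non-positive total intensity are flagged invalid (NaN).
    Returns ``None`` when more than ``max_invalid_fraction`` of frames are
    invalid. E is not clipped to [0, 1]; noise excursions are retained.
    """
    total = trace.donor + trace.acceptor
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, trace.acceptor / total, np.nan)
    if np.mean(~np.isfinite(e)) > max_invalid_fraction:
        return None
    return FRETTrace(trace.trace_id, e, trace.frame_interval)


def select_and_truncate(
    traces: Iterable[RawTrace],
    rules: QCRules | None = None,
) -> tuple[list[FRETTrace], list[QCReport]]:
    """Apply the full selection chain; every input gets a QC report."""
    rules = rules or QCRules()
    accepted: list[FRETTrace] = []
    reports: list[QCReport] = []

    for raw in traces:
        corrected = correct_bleedthrough(raw, rules.beta)
        steps = detect_bleach_steps(corrected, rules)
        per_channel = {"donor": [f for c, f in steps if c == "donor"],
                       "acceptor": [f for c, f in steps if c == "acceptor"]}
        bleach_frame = steps[0][1] if steps else None
        cut = bleach_frame if bleach_frame is not None else len(raw)

        def _report(ok: bool, reason: RejectionReason | None, r: float | None = None,
                    length: int | None = None) -> QCReport:
            return QCReport(raw.trace_id, ok, reason, bleach_frame,
                            cut if length is None else length, r)

        if any(len(v) > rules.max_bleach_steps for v in per_channel.values()):
            reports.append(_report(False, "multi_step_bleach"))
            continue
        # lifetime of each dye = first step in that channel (or full length)
        lifetimes = [v[0] if v else len(raw) for v in per_channel.values()]
        if min(min(lifetimes), cut) < rules.min_lifetime:
            reports.append(_report(False, "short_lifetime"))
            continue

        truncated = RawTrace(raw.trace_id, corrected.donor[:cut],
                             corrected.acceptor[:cut], raw.frame_interval)
        r = check_anticorrelation(truncated)
        if rules.anticorrelation_threshold is not None:
            if not np.isfinite(r) or r > rules.anticorrelation_threshold:
                reports.append(_report(False, "not_anticorrelated", r))
                continue

        smoothed = RawTrace(raw.trace_id,
                            smooth(truncated.donor, rules.smooth_window),
                            smooth(truncated.acceptor, rules.smooth_window),
                            raw.frame_interval)
        fret = compute_fret(smoothed, rules.max_invalid_fraction)
        if fret is None:
            reports.append(_report(False, "other", r))
            continue
        accepted.append(fret)
        reports.append(_report(True, None, r))
    return accepted, reports
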