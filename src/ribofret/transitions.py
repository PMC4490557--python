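"""Transition extraction, static/dynamic classification, post-synchronization.

Two filters are applied to idealized trajectories before any event is
counted, mirroring how noise-level excursions are excluded from kinetic
analysis: level changes smaller than 0.05 FRET are merged into the
surrounding dwell, and dwells lasting a single frame are merged into a
neighbor. The one-frame merge runs first (into the neighbor with the
closer level, ties to the earlier dwell), then the small-amplitude merge.

Post-synchronization aligns trajectories at the first transition into a
canonical class with center <= 0.5, so that the onset of tRNA
translocation coincides across molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .idealization import CanonicalMap, IdealizedTrace, LT_CANONICAL

__all__ = [
    "Segment",
    "Transition",
    "TraceClass",
    "SyncedTrace",
    "merge_segments",
    "segment_trace",
    "extract_transitions",
    "classify_static_dynamic",
    "postsynchronize",
    "count_transition_types",
]

MIN_DELTA = 0.05
MIN_DWELL_FRAMES = 2


@dataclass
class Segment:
    """A dwell in the filtered idealized trajectory."""

    level: float
    canonical_class: str | None
    start: int
    length: int
    sd: float = 0.0          # fitted emission SD of the occupying state

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Transition:
    trace_id: str
    frame: int            # first frame of the destination dwell
    time: float           # frame * frame_interval
    from_class: str | None
    to_class: str | None
    from_level: float
    to_level: float

    @property
    def delta(self) -> float:
        return self.to_level - self.from_level


@dataclass(frozen=True)
class TraceClass:
    trace_id: str
    label: Literal["static", "dynamic"]
    n_transitions: int
    scope: str


@dataclass
class SyncedTrace:
    """A trajectory re-indexed so aligned frame 0 is the sync transition."""

    trace_id: str
    sync_frame: int
    aligned_frames: np.ndarray        # negative before the sync point
    efficiency: np.ndarray | None
    classes: tuple[str | None, ...]
    frame_interval: float


def _raw_segments(ideal: IdealizedTrace) -> list[Segment]:
    levels = np.asarray(ideal.level_mean, float)
    classes = ideal.canonical_class or (None,) * len(levels)
    try:
        sds = ideal.model.emission_sd[ideal.state_index]
    except (AttributeError, TypeError, IndexError):
        sds = np.zeros(len(levels))
    change = np.flatnonzero(np.diff(levels) != 0.0) + 1
    bounds = np.concatenate([[0], change, [len(levels)]])
    return [Segment(float(levels[a]), classes[a], int(a), int(b - a),
                    float(sds[a]))
            for a, b in zip(bounds[:-1], bounds[1:])]


def _merge_pair(segs: list[Segment], idx: int, into: int) -> None:
    """Absorb segment ``idx`` into neighbor ``into``; fuse equal levels."""
    segs[into].length += segs[idx].length
    if into > idx:
        segs[into].start = segs[idx].start
    del segs[idx]
    # fusing may create adjacent same-level segments; join them
    j = min(idx, into)
    j = max(j - 1, 0)
    while j < len(segs) - 1:
        if segs[j].level == segs[j + 1].level:
            segs[j].length += segs[j + 1].length
            del segs[j + 1]
        else:
            j += 1


RESOLVABILITY_FACTOR = 1.5
SD_INFLATION = np.sqrt(3.0)     # raw-equivalent of a 3-point-smoothed SD
# canonical states are >= 0.2 apart and fitted means carry ~0.02 noise,
# so a genuine cross-state level change is never below ~0.16; the
# noise-resolvability merge must not reach that scale even when blur
# frames inflate the fitted SDs
MAX_RESOLVABILITY = 0.15


def merge_segments(segs: Sequence[Segment],
                   min_delta: float = MIN_DELTA,
                   min_dwell: int = MIN_DWELL_FRAMES) -> list[Segment]:
    """Apply the one-frame-dwell and small-amplitude filters.

    One-frame (more generally sub-``min_dwell``) dwells are merged into
    the neighbor with the closer level (ties to the earlier neighbor).
    Afterwards, adjacent dwells are fused when their levels differ by
    less than ``min_delta`` or by less than 1.5 pooled raw-equivalent
    emission SDs -- level changes below the emission spread cannot be
    distinguished from noise (broad states split by the HMM produce
    exactly such sub-resolution level pairs). The fused dwell keeps the
    level, class and SD of its longer member, so repeated merging cannot
    walk the level across a genuine state boundary.
    """
    segs = [Segment(s.level, s.canonical_class, s.start, s.length, s.sd)
            for s in segs]

    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, s in enumerate(segs):
            if s.length < min_dwell:
                if i == 0:
                    target = 1
                elif i == len(segs) - 1:
                    target = i - 1
                else:
                    d_prev = abs(s.level - segs[i - 1].level)
                    d_next = abs(s.level - segs[i + 1].level)
                    target = i - 1 if d_prev <= d_next else i + 1
                _merge_pair(segs, i, target)
                changed = True
                break

    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            pooled_sd = np.sqrt(0.5 * (a.sd ** 2 + b.sd ** 2))
            resolvable = max(min_delta,
                             min(RESOLVABILITY_FACTOR * SD_INFLATION
                                 * pooled_sd, MAX_RESOLVABILITY))
            if abs(a.level - b.level) < resolvable:
                keep = a if a.length >= b.length else b
                segs[i] = Segment(keep.level, keep.canonical_class, a.start,
                                  a.length + b.length, keep.sd)
                del segs[i + 1]
                changed = True
                break
    return segs


def remove_transit_blur(segs: list[Segment],
                        blur_frames: int = 2) -> list[Segment]:
    """Remove short monotone pass-through dwells created by smoothing.

    A sharp level change, once smoothed over three points, spends up to
    two frames at intermediate values; the HMM renders these as a short
    dwell between the true levels, splitting one direct transition into a
    staircase. A dwell of at most ``blur_frames`` whose neighbors
    straddle its level monotonically is therefore treated as being in
    transit: its frames are divided between the flanking dwells and the
    direct transition is restored.
    """
    segs = list(segs)
    i = 1
    while i < len(segs) - 1:
        a, s, b = segs[i - 1], segs[i], segs[i + 1]
        monotone = (a.level > s.level > b.level) or (a.level < s.level < b.level)
        if s.length <= blur_frames and monotone:
            take = s.length // 2
            a.length += take
            b.start = s.start + take
            b.length += s.length - take
            del segs[i]
        else:
            i += 1
    return segs


def segment_trace(ideal: IdealizedTrace,
                  min_delta: float = MIN_DELTA,
                  min_dwell: int = MIN_DWELL_FRAMES,
                  blur_frames: int = 2) -> list[Segment]:
    """Filtered dwell list of one idealized trace.

    After the amplitude and duration filters, sub-blur monotone
    pass-through dwells are reattributed to their flanking dwells
    (:func:`remove_transit_blur`), and consecutive dwells carrying
    the same canonical class are fused: distinct fitted levels inside one
    class (e.g. a residual transition-blur level flanking a genuine
    dwell) are one sojourn of that state, not a transition.
    """
    segs = merge_segments(_raw_segments(ideal), min_delta, min_dwell)
    segs = remove_transit_blur(segs, blur_frames)
    i = 0
    while i < len(segs) - 1:
        a, b = segs[i], segs[i + 1]
        if a.canonical_class is not None and a.canonical_class == b.canonical_class:
            w = a.length + b.length
            segs[i] = Segment((a.level * a.length + b.level * b.length) / w,
                              a.canonical_class, a.start, w)
            del segs[i + 1]
        else:
            i += 1
    return segs


def extract_transitions(ideals: Iterable[IdealizedTrace],
                        min_delta: float = MIN_DELTA,
                        min_dwell: int = MIN_DWELL_FRAMES
                        ) -> list[Transition]:
    """Filtered state-change events of a set of idealized traces."""
    out: list[Transition] = []
    for ideal in ideals:
        segs = segment_trace(ideal, min_delta, min_dwell)
        for a, b in zip(segs[:-1], segs[1:]):
            out.append(Transition(
                trace_id=ideal.trace_id,
                frame=b.start,
                time=b.start * ideal.frame_interval,
                from_class=a.canonical_class,
                to_class=b.canonical_class,
                from_level=a.level,
                to_level=b.level,
            ))
    return out


def classify_static_dynamic(
    ideals: Iterable[IdealizedTrace],
    transitions: Iterable[Transition],
    scope: str = "full",
    sync_frames: dict[str, int] | None = None,
) -> list[TraceClass]:
    """Label each trace static (no filtered transition in scope) or dynamic.

    ``scope`` is ``"full"`` (whole record), ``"pre_sync"`` (frames before
    the sync transition) or ``"post_sync"``; the latter two require
    ``sync_frames``. A trace absent from ``sync_frames`` is judged over
    its whole record.
    """
    by_trace: dict[str, int] = {}
    for tr in transitions:
        t0 = (sync_frames or {}).get(tr.trace_id)
        if scope == "pre_sync" and t0 is not None and tr.frame >= t0:
            continue
        if scope == "post_sync" and t0 is not None and tr.frame <= t0:
            continue
        by_trace[tr.trace_id] = by_trace.get(tr.trace_id, 0) + 1
    out = []
    for ideal in ideals:
        n = by_trace.get(ideal.trace_id, 0)
        out.append(TraceClass(ideal.trace_id,
                              "dynamic" if n > 0 else "static", n, scope))
    return out


def postsynchronize(
    ideals: Iterable[IdealizedTrace],
    fret_traces: Iterable | None = None,
    canonical: CanonicalMap = LT_CANONICAL,
    threshold: float = 0.5,
    min_delta: float = MIN_DELTA,
    min_dwell: int = MIN_DWELL_FRAMES,
) -> tuple[list[SyncedTrace], list[str]]:
    """Align traces at the first transition into a class with center <= 0.5.

    The criterion is evaluated on canonical class centers of the filtered
    dwell sequence, not on raw efficiency, so noise excursions cannot
    trigger a spurious synchronization point. Traces that never make such
    a transition -- including any trace that already starts below the
    threshold and never re-enters it from above -- are excluded and their
    ids returned separately.
    """
    eff = {t.trace_id: t.efficiency for t in (fret_traces or [])}
    synced: list[SyncedTrace] = []
    excluded: list[str] = []
    for ideal in ideals:
        segs = segment_trace(ideal, min_delta, min_dwell)
        sync = None
        for prev, seg in zip(segs[:-1], segs[1:]):
            c_prev = (canonical.center_of(prev.canonical_class)
                      if prev.canonical_class else prev.level)
            c_this = (canonical.center_of(seg.canonical_class)
                      if seg.canonical_class else seg.level)
            if c_prev > threshold and c_this <= threshold:
                sync = seg.start
                break
        if sync is None:
            excluded.append(ideal.trace_id)
            continue
        n = len(ideal)
        classes = ideal.canonical_class or (None,) * n
        synced.append(SyncedTrace(
            trace_id=ideal.trace_id,
            sync_frame=sync,
            aligned_frames=np.arange(n) - sync,
            efficiency=eff.get(ideal.trace_id),
            classes=tuple(classes),
            frame_interval=ideal.frame_interval,
        ))
    return synced, excluded


_TYPE_PAIRS = (frozenset({"0.8", "0.6"}), frozenset({"0.6", "0.4"}),
               frozenset({"0.4", "0.2"}))


def count_transition_types(
    transitions: Iterable[Transition],
    trace_classes: Iterable[TraceClass] | None = None,
) -> dict[str, float]:
    """Fractions of 0.8<->0.6, 0.6<->0.4 and 0.4<->0.2 events.

    Counted among dynamic traces when ``trace_classes`` is given;
    transitions between other class pairs are reported under
    ``"other"``. Returns an empty dict when no transition is counted.
    """
    dynamic = None
    if trace_classes is not None:
        dynamic = {c.trace_id for c in trace_classes if c.label == "dynamic"}
    counts = {pair: 0 for pair in _TYPE_PAIRS}
    other = 0
    for tr in transitions:
        if dynamic is not None and tr.trace_id not in dynamic:
            continue
        pair = frozenset({tr.from_class, tr.to_class})
        if pair in counts:
            counts[pair] += 1
        else:
            other += 1
    total = sum(counts.values()) + other
    if total == 0:
        return {}
    out = {"<->".join(sorted(pair, reverse=True)): counts[pair] / total
           for pair in _TYPE_PAIRS}
    out["other"] = other / total
    return out
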