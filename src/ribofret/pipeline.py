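"""End-to-end analysis: QC -> idealization -> transitions -> populations
-> kinetics, with tabular export of every stage."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import PipelineConfig
from .idealization import (LT_CANONICAL, TT_CANONICAL, IdealizedTrace,
                           idealize_traces)
from .kinetics import RateEstimate, estimate_bleach_rate, estimate_rates, \
    summarize_rate_table
from .populations import build_contour, build_histogram, compute_populations
from .trace_qc import FRETTrace, QCReport, RawTrace, select_and_truncate
from .transitions import (SyncedTrace, TraceClass, Transition,
                          classify_static_dynamic, count_transition_types,
                          extract_transitions, postsynchronize)

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    condition: str
    config: PipelineConfig
    qc_reports: list[QCReport]
    fret_traces: list[FRETTrace]
    ideals: list[IdealizedTrace]
    transitions: list[Transition]
    trace_classes: list[TraceClass]
    synced: list[SyncedTrace]
    sync_excluded: list[str]
    populations: pd.Series
    rates: list[RateEstimate]
    rate_table: pd.DataFrame
    transition_type_fractions: dict[str, float]
    k_bleach: float | None

    @property
    def n_accepted(self) -> int:
        return len(self.fret_traces)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_table(_io.qc_reports_frame(self.qc_reports),
                        outdir / "qc_report.tsv")
        _io.write_table(pd.concat([
            pd.DataFrame({"trace_id": t.trace_id,
                          "frame": np.arange(len(t)),
                          "efficiency": t.efficiency})
            for t in self.fret_traces], ignore_index=True)
            if self.fret_traces else
            pd.DataFrame(columns=["trace_id", "frame", "efficiency"]),
            outdir / "fret_traces.tsv")
        _io.write_table(pd.concat([
            pd.DataFrame({"trace_id": i.trace_id,
                          "frame": np.arange(len(i)),
                          "level_mean": i.level_mean,
                          "canonical_class": [c or "" for c in i.canonical_class]})
            for i in self.ideals], ignore_index=True)
            if self.ideals else
            pd.DataFrame(columns=["trace_id", "frame", "level_mean",
                                  "canonical_class"]),
            outdir / "idealized.tsv")
        _io.write_table(pd.DataFrame([{
            "trace_id": i.trace_id,
            "n_states": i.model.n_states,
            "bic": i.score,
            "means": ",".join(f"{m:.4f}" for m in i.model.emission_mean),
            "flags": ";".join(i.quality_flags),
        } for i in self.ideals]), outdir / "models.tsv")
        _io.write_table(pd.DataFrame([{
            "trace_id": t.trace_id, "frame": t.frame, "time": t.time,
            "from_class": t.from_class or "", "to_class": t.to_class or "",
            "delta": t.delta,
        } for t in self.transitions]), outdir / "transitions.tsv")
        _io.write_table(pd.DataFrame([asdict(c) for c in self.trace_classes]),
                        outdir / "trace_classes.tsv")
        _io.write_table(pd.DataFrame([{
            "trace_id": s.trace_id, "sync_frame": s.sync_frame,
        } for s in self.synced]), outdir / "sync_frames.tsv")
        _io.write_table(
            self.populations.rename_axis("state").reset_index(name="P"),
            outdir / "populations.tsv")
        _io.write_table(self.rate_table, outdir / "rate_table.tsv")
        if self.synced:
            mat, frames, edges = build_contour(
                self.synced, window=self.config.histogram_window,
                pre_frames=min(15, self.config.histogram_window))
            contour = pd.DataFrame(
                mat, index=pd.Index(frames, name="aligned_frame"),
                columns=[f"{c:.4f}" for c in 0.5 * (edges[:-1] + edges[1:])])
            _io.write_table(contour.reset_index(), outdir / "contour.tsv")
        manifest = {"condition": self.condition,
                    "config": asdict(self.config),
                    "n_input": len(self.qc_reports),
                    "n_accepted": self.n_accepted}
        _io.write_manifest(manifest, outdir / "manifest.yaml")


def analyze(raw_traces: list[RawTrace], config: PipelineConfig | None = None,
            condition: str = "unknown") -> AnalysisResult:
    """Run the complete analysis chain on raw intensity traces.

    Raises ``RuntimeError`` when no trace survives QC (a run with nothing
    to analyze is an error, not an empty result).
    """
    config = config or PipelineConfig()
    canonical = LT_CANONICAL if config.canonical == "lt" else TT_CANONICAL

    fret_traces, qc_reports = select_and_truncate(raw_traces, config.qc)
    if not fret_traces:
        raise RuntimeError("no accepted traces after quality control")

    ideals = idealize_traces(fret_traces, config.k_max, canonical,
                             seed=config.seed, options=config.hmm)
    if config.exclude_flagged:
        kept_ids = {i.trace_id for i in ideals if not i.flagged}
        ideals = [i for i in ideals if i.trace_id in kept_ids]
        fret_traces = [t for t in fret_traces if t.trace_id in kept_ids]

    transitions = extract_transitions(ideals, config.min_delta,
                                      config.min_dwell_frames)
    synced, excluded = postsynchronize(
        ideals, fret_traces, canonical, config.sync_threshold,
        config.min_delta, config.min_dwell_frames)
    sync_frames = {s.trace_id: s.sync_frame for s in synced}
    trace_classes = classify_static_dynamic(ideals, transitions, "full")

    use_sync = bool(synced)
    if config.sync_populations == "never":
        use_sync = False
    elif config.sync_populations == "auto":
        use_sync = len(synced) >= 0.5 * len(ideals) and bool(synced)
    if use_sync:
        populations = compute_populations(ideals, config.histogram_window,
                                          sync_frames)
    else:
        populations = compute_populations(ideals, None)

    accepted_reports = [r for r in qc_reports if r.accepted]
    try:
        k_bleach = estimate_bleach_rate(
            accepted_reports, raw_traces[0].frame_interval)
    except ValueError:
        k_bleach = None
    n_static = sum(1 for c in trace_classes if c.label == "static")
    rates = estimate_rates(
        ideals, accepted_reports, k_bleach=k_bleach or 0.0,
        min_dwells=config.min_dwells_for_fit,
        dead_time=config.dead_time_frames * raw_traces[0].frame_interval,
        static_adjustment=config.static_adjustment,
        n_static=n_static, n_dynamic=len(trace_classes) - n_static,
        min_delta=config.min_delta, min_dwell=config.min_dwell_frames)
    rate_table = summarize_rate_table(condition, populations, rates, canonical)
    fractions = count_transition_types(transitions, trace_classes)

    return AnalysisResult(
        condition=condition, config=config, qc_reports=qc_reports,
        fret_traces=fret_traces, ideals=ideals, transitions=transitions,
        trace_classes=trace_classes, synced=synced, sync_excluded=excluded,
        populations=populations, rates=rates, rate_table=rate_table,
        transition_type_fractions=fractions, k_bleach=k_bleach)
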