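"""Tab-delimited readers/writers and run manifests.

All tables are UTF-8, tab-delimited with a header row; floats are
written at six significant digits. Every output directory receives a
manifest naming the software version, the configuration snapshot and the
SHA-256 checksums of its inputs, so each stage's provenance is explicit.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .trace_qc import RawTrace, QCReport

__all__ = [
    "write_table",
    "read_table",
    "read_traces",
    "save_dataset",
    "load_dataset",
    "qc_reports_frame",
    "write_manifest",
    "file_checksum",
]

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_traces(path, frame_interval: float) -> list[RawTrace]:
    """Load a trace table (trace_id, frame, donor, acceptor) as RawTraces."""
    df = read_table(path)
    required = {"trace_id", "frame", "donor", "acceptor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table {path} lacks columns: {sorted(missing)}")
    out = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        out.append(RawTrace(str(tid), g["donor"].to_numpy(float),
                            g["acceptor"].to_numpy(float), frame_interval))
    return out


def save_dataset(dataset, outdir) -> dict[str, Path]:
    """Write trace table, ground-truth sidecars and manifest for a dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": write_table(dataset.traces, outdir / "traces.tsv"),
        "truth_frames": write_table(dataset.truth_frames,
                                    outdir / "ground_truth_frames.tsv"),
        "truth_traces": write_table(dataset.truth_traces,
                                    outdir / "ground_truth_traces.tsv"),
    }
    manifest = dict(dataset.manifest)
    manifest["checksums"] = {k: file_checksum(p) for k, p in paths.items()}
    write_manifest(manifest, outdir / "manifest.yaml")
    return paths


def load_dataset(indir):
    """Reload a saved dataset directory into a SimulatedDataset."""
    from .synthetic import SimulatedDataset, KineticScheme

    indir = Path(indir)
    manifest = yaml.safe_load((indir / "manifest.yaml").read_text())
    sch = manifest["scheme"]
    scheme = KineticScheme(
        state_names=tuple(sch["state_names"]),
        fret_mean=np.asarray(sch["fret_mean"]),
        fret_sd=np.asarray(sch["fret_sd"]),
        rate_matrix=np.asarray(sch["rate_matrix"]),
    )
    return SimulatedDataset(
        traces=read_table(indir / "traces.tsv"),
        truth_frames=read_table(indir / "ground_truth_frames.tsv"),
        truth_traces=read_table(indir / "ground_truth_traces.tsv"),
        manifest=manifest,
        scheme=scheme,
    )


def qc_reports_frame(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trace_id": r.trace_id,
        "accepted": r.accepted,
        "reason": r.rejection_reason or "",
        "bleach_frame": r.bleach_frame if r.bleach_frame is not None else "",
        "truncated_length": r.truncated_length,
        "anticorrelation": r.anticorrelation,
    } for r in reports])


def write_manifest(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"software": "ribofret", "version": __version__, **data}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
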