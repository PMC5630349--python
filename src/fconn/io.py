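"""Delimited-text readers and writers.

Everything on disk is plain text by design: the pipeline starts from
ROI time series, not image volumes.

File conventions:

* time-series files — tab-delimited, one header line of ROI labels,
  then the ROI-by-frame signal matrix (ROIs as rows);
* motion files — six whitespace-delimited columns per frame
  (x, y, z translations in mm; pitch, roll, yaw rotations in degrees);
* manifest — tab-delimited table with at least ``subject_id`` and
  ``group`` columns, plus covariates and behavioral scores;
* connectivity matrices — tab-delimited square matrices;
* edge lists and BrainNet-style ``.node``/``.edge`` exports use
  1-based node indices matching the region table convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fconn.errors import ValidationError
from fconn.network import BinaryGraph, ConnectivityMatrix
from fconn.prep import MotionTrace, SubjectTimeSeries
from fconn.synth import SyntheticDataset

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_motion",
    "read_motion",
    "write_manifest",
    "read_manifest",
    "write_connectivity",
    "read_connectivity",
    "write_edge_list",
    "write_brainnet",
    "write_dataset",
]


def write_timeseries(path: Path | str, ts: SubjectTimeSeries) -> None:
    path = Path(path)
    header = "\t".join(ts.roi_labels)
    body = "\n".join(
        "\t".join(f"{v:.10g}" for v in row) for row in ts.data
    )
    path.write_text(header + "\n" + body + "\n")


def read_timeseries(
    path: Path | str, tr_seconds: float, subject_id: str | None = None
) -> SubjectTimeSeries:
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if len(lines) < 2:
        raise ValidationError(f"{path}: no data rows")
    labels = tuple(lines[0].rstrip("\n").split("\t"))
    try:
        data = np.array(
            [[float(v) for v in line.split()] for line in lines[1:]]
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    if data.shape[0] != len(labels):
        raise ValidationError(
            f"{path}: {len(labels)} ROI labels but {data.shape[0]} signal rows"
        )
    return SubjectTimeSeries(
        data=data, tr_seconds=tr_seconds, roi_labels=labels,
        subject_id=subject_id or path.stem,
    )


def write_motion(path: Path | str, motion: MotionTrace) -> None:
    np.savetxt(path, motion.params, fmt="%.8g")


def read_motion(path: Path | str, subject_id: str | None = None) -> MotionTrace:
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ValidationError(
                f"{path}, line {lineno}: expected 6 motion columns, "
                f"got {len(fields)}"
            )
        try:
            rows.append([float(v) for v in fields])
        except ValueError as exc:
            raise ValidationError(
                f"{path}, line {lineno}: non-numeric cell ({exc})"
            ) from exc
    if not rows:
        raise ValidationError(f"{path}: empty motion file")
    return MotionTrace(params=np.array(rows), subject_id=subject_id or path.stem)


def write_manifest(path: Path | str, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    manifest = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group"):
        if col not in manifest.columns:
            raise ValidationError(f"{path}: manifest missing column {col!r}")
    if manifest["subject_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate subject ids")
    return manifest


def write_connectivity(path: Path | str, cm: ConnectivityMatrix) -> None:
    np.savetxt(path, cm.z, fmt="%.10g", delimiter="\t",
               header="\t".join(cm.node_labels), comments="")


def read_connectivity(path: Path | str) -> ConnectivityMatrix:
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    labels = tuple(lines[0].split("\t"))
    z = np.array([[float(v) for v in line.split()] for line in lines[1:]])
    return ConnectivityMatrix(z=z, node_labels=labels, subject_id=path.stem)


def write_edge_list(path: Path | str, graph: BinaryGraph) -> None:
    """Tab-delimited (i, j) pairs, 1-based, i < j."""
    with open(path, "w") as fh:
        for i, j in graph.edge_list():
            fh.write(f"{i + 1}\t{j + 1}\n")


def write_brainnet(
    stem: Path | str,
    graph: BinaryGraph,
    node_values: np.ndarray | None = None,
    coordinates: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """BrainNet-style ``.node`` and ``.edge`` text files for visualization.

    Without supplied coordinates the nodes are placed on a circle —
    adequate for schematic rendering of synthetic networks.
    """
    stem = Path(stem)
    n = graph.n_nodes
    if coordinates is None:
        theta = 2 * np.pi * np.arange(n) / n
        coordinates = np.column_stack(
            [70 * np.cos(theta), 70 * np.sin(theta), np.zeros(n)]
        )
    values = np.ones(n) if node_values is None else np.asarray(node_values)
    node_path = stem.with_suffix(".node")
    with open(node_path, "w") as fh:
        for i in range(n):
            x, y, z = coordinates[i]
            fh.write(
                f"{x:.2f}\t{y:.2f}\t{z:.2f}\t1\t{values[i]:.6g}\t"
                f"{graph.node_labels[i]}\n"
            )
    edge_path = stem.with_suffix(".edge")
    np.savetxt(edge_path, graph.adjacency, fmt="%d", delimiter="\t")
    return node_path, edge_path


def write_dataset(dataset: SyntheticDataset, outdir: Path | str) -> Path:
    """Write a synthetic study: per-subject series + motion, manifest,
    and a ground-truth sidecar (JSON) for recovery tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "timeseries").mkdir(exist_ok=True)
    (outdir / "motion").mkdir(exist_ok=True)
    for ts, motion in zip(dataset.timeseries, dataset.motions):
        write_timeseries(outdir / "timeseries" / f"{ts.subject_id}.tsv", ts)
        write_motion(outdir / "motion" / f"{motion.subject_id}.txt", motion)
    write_manifest(outdir / "manifest.tsv", dataset.manifest)
    spec = dataset.spec
    truth = {
        "spec": {
            "n_nodes": spec.n_nodes,
            "n_subjects_per_group": spec.n_subjects_per_group,
            "n_timepoints": spec.n_timepoints,
            "tr_seconds": spec.tr_seconds,
            "k": spec.k,
            "beta": spec.beta,
            "affected_nodes": list(spec.affected_nodes),
            "degradation_fraction": spec.degradation_fraction,
            "edge_weight": spec.edge_weight,
            "noise_sd": spec.noise_sd,
            "spike_probability": spec.spike_probability,
            "spike_amplitude_mm": spec.spike_amplitude_mm,
            "behavior_slope": spec.behavior_slope,
            "behavior_noise_sd": spec.behavior_noise_sd,
            "seed": spec.seed,
        },
        "subjects": {
            sid: {
                "edges": [[i + 1, j + 1] for i, j in graph.edge_list()],
                "spike_frames": [
                    int(f) for f in row.split(",") if f
                ],
            }
            for sid, graph, row in zip(
                dataset.subject_ids,
                dataset.true_graphs,
                dataset.manifest["true_spike_frames"],
            )
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return outdir
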