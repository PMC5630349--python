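"""End-to-end orchestration of the connectome analysis.

``load_study`` assembles a validated bundle (aligned subjects, groups,
covariates, behavioral scores); ``run_all`` executes
preprocessing -> network construction -> graph metrics -> inference and
writes every table, a machine-readable summary and a log capturing
seeds, thresholds and exclusion counts. Two runs with the same
configuration and data produce byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fconn import io as fio
from fconn.config import StudyConfig
from fconn.errors import ComputationError, ValidationError
from fconn.graph_metrics import (
    GLOBAL_METRIC_NAMES,
    auc,
    cost_efficiency,
    global_metrics,
    nodal_metrics_table,
)
from fconn.network import (
    SparsityGrid,
    binarize_at_sparsity,
    correlation_matrix,
    minimum_sparsity,
)
from fconn.prep import preprocess_subject
from fconn.stats import (
    behavior_correlation_screen,
    global_metric_comparison,
    per_node_threshold,
    permutation_test_nodal,
)
from fconn.synth import SCORE_COLUMNS

__all__ = ["StudyBundle", "RunReport", "load_study", "run_all"]

logger = logging.getLogger(__name__)

#: Nodal metrics compared between groups and screened against behavior.
NODAL_METRICS = ("degree", "nodal_efficiency", "betweenness")


@dataclass
class StudyBundle:
    """Aligned per-subject inputs plus manifest-level metadata."""

    config: StudyConfig
    manifest: pd.DataFrame
    timeseries: list  # SubjectTimeSeries, manifest order
    motions: list  # MotionTrace, manifest order

    @property
    def subject_ids(self) -> list[str]:
        return self.manifest["subject_id"].tolist()

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.manifest["group"] == group).to_numpy())


@dataclass
class RunReport:
    """All result tables of one full run."""

    qc: pd.DataFrame
    grid: SparsityGrid
    global_curves: dict[str, dict[str, np.ndarray]]  # metric -> group -> array
    global_comparison: pd.DataFrame
    nodal_auc: dict[str, np.ndarray]  # metric -> (subjects x nodes)
    nodal_permutation: pd.DataFrame
    behavior_all: pd.DataFrame | None
    behavior_group_b: pd.DataFrame | None
    cost_efficiency_argmax: dict[str, float]
    summary: dict = field(default_factory=dict)


def load_study(config: StudyConfig) -> StudyBundle:
    """Read and cross-validate manifest, time-series and motion files.

    Every manifest subject must have exactly one time-series file and
    one motion file; orphans on either side are reported by id.
    """
    manifest = fio.read_manifest(config.manifest)
    ts_dir = Path(config.timeseries_dir)
    motion_dir = Path(config.motion_dir)
    ts_files = {p.stem: p for p in sorted(ts_dir.glob("*.tsv"))}
    missing = [s for s in manifest["subject_id"] if s not in ts_files]
    if missing:
        raise ValidationError(
            f"manifest subjects without time-series files: {missing}"
        )
    orphans = sorted(set(ts_files) - set(manifest["subject_id"]))
    if orphans:
        raise ValidationError(
            f"time-series files without manifest entries: {orphans}"
        )
    timeseries, motions = [], []
    for sid in manifest["subject_id"]:
        ts = fio.read_timeseries(ts_files[sid], config.tr_seconds, subject_id=sid)
        motion_path = motion_dir / f"{sid}.txt"
        if not motion_path.exists():
            raise ValidationError(f"no motion file for subject {sid!r}")
        motion = fio.read_motion(motion_path, subject_id=sid)
        if motion.n_frames != ts.n_frames:
            raise ValidationError(
                f"subject {sid!r}: {motion.n_frames} motion frames vs "
                f"{ts.n_frames} signal frames"
            )
        timeseries.append(ts)
        motions.append(motion)
    return StudyBundle(
        config=config, manifest=manifest, timeseries=timeseries, motions=motions
    )


def _build_grid(config: StudyConfig, n_nodes: int) -> SparsityGrid:
    net = config.network
    smin = net.sparsity_min
    if smin is None:
        smin = minimum_sparsity(n_nodes, net.step)
        logger.info("auto minimum sparsity for N=%d: %.3g", n_nodes, smin)
    return SparsityGrid.from_range(smin, net.sparsity_max, net.step)


def run_all(config: StudyConfig, write: bool = True) -> RunReport:
    """Execute the full analysis on the configured study.

    Stages: per-subject preprocessing (FD, drop, detrend, bandpass,
    nuisance regression, scrubbing) -> Fisher-z connectivity ->
    binarization across the sparsity grid -> global and nodal metrics
    with degree-preserving nulls -> AUCs -> group t-tests, nodal
    permutation tests (age + mean FD adjusted) and behavioral partial
    correlations.
    """
    bundle = load_study(config)
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        return _run_all_inner(bundle, config, outdir, write)
    finally:
        if write:
            logger.removeHandler(handler)
            handler.close()


def _run_all_inner(
    bundle: StudyBundle, config: StudyConfig, outdir: Path, write: bool
) -> RunReport:
    logger.info(
        "run-all: %d subjects, fd_threshold=%g mm, band=[%g, %g] Hz, "
        "n_drop=%d, metrics seed=%d, n_random=%d, stats seed=%d, n_perm=%d",
        len(bundle.subject_ids), config.prep.fd_threshold_mm,
        config.prep.low_hz, config.prep.high_hz, config.prep.n_drop,
        config.metrics.seed, config.metrics.n_random,
        config.stats.seed, config.stats.n_perm,
    )

    # ---- preprocessing -------------------------------------------------
    qc_rows = []
    cleaned = []
    for ts, motion in zip(bundle.timeseries, bundle.motions):
        try:
            result = preprocess_subject(
                ts, motion,
                n_drop=config.prep.n_drop,
                low_hz=config.prep.low_hz,
                high_hz=config.prep.high_hz,
                fd_threshold_mm=config.prep.fd_threshold_mm,
                regress_motion=config.prep.regress_motion,
            )
        except (ValidationError, ComputationError) as exc:
            raise ComputationError(
                f"preprocessing failed for subject {ts.subject_id!r}: {exc}"
            ) from exc
        cleaned.append(result.timeseries)
        qc_rows.append(
            {
                "subject_id": ts.subject_id,
                "mean_fd": result.mean_fd,
                "n_scrubbed": result.n_scrubbed,
                "n_frames_retained": result.timeseries.n_frames,
            }
        )
        logger.info(
            "prep %s: mean FD %.4f mm, scrubbed %d frame(s), %d retained",
            ts.subject_id, result.mean_fd, result.n_scrubbed,
            result.timeseries.n_frames,
        )
    qc = pd.DataFrame(qc_rows)
    manifest = bundle.manifest.merge(qc, on="subject_id")

    # ---- networks and metrics -----------------------------------------
    n_nodes = cleaned[0].n_rois
    grid = _build_grid(config, n_nodes)
    logger.info(
        "sparsity grid: %.3g..%.3g step %.3g (%d points)",
        grid.values[0], grid.values[-1], grid.step, len(grid),
    )
    metric_seeds = np.random.SeedSequence(config.metrics.seed).spawn(
        len(cleaned)
    )
    n_subj = len(cleaned)
    global_curves_subj = {
        m: np.zeros((n_subj, len(grid))) for m in GLOBAL_METRIC_NAMES
    }
    nodal_curves = {
        m: np.zeros((n_subj, len(grid), n_nodes)) for m in NODAL_METRICS
    }
    for s_idx, ts in enumerate(cleaned):
        try:
            cm = correlation_matrix(ts)
        except ComputationError as exc:
            raise ComputationError(
                f"network construction failed for {ts.subject_id!r}: {exc}"
            ) from exc
        subj_seeds = metric_seeds[s_idx].spawn(len(grid))
        for g_idx, s in enumerate(grid.values):
            graph = binarize_at_sparsity(cm, float(s))
            gm = global_metrics(
                graph,
                n_random=config.metrics.n_random,
                seed=int(subj_seeds[g_idx].generate_state(1)[0] % (2**31)),
            )
            for m in GLOBAL_METRIC_NAMES:
                global_curves_subj[m][s_idx, g_idx] = gm[m]
            nm = nodal_metrics_table(graph)
            for m in NODAL_METRICS:
                nodal_curves[m][s_idx, g_idx] = nm[m]
        logger.info("metrics done for %s", ts.subject_id)

    # ---- AUCs ----------------------------------------------------------
    nodal_auc = {
        m: np.array(
            [[auc(nodal_curves[m][s, :, i], grid) for i in range(n_nodes)]
             for s in range(n_subj)]
        )
        for m in NODAL_METRICS
    }
    idx_a = bundle.group_indices("A")
    idx_b = bundle.group_indices("B")
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValidationError("both groups A and B must be present")

    global_curves = {
        m: {"A": global_curves_subj[m][idx_a], "B": global_curves_subj[m][idx_b]}
        for m in GLOBAL_METRIC_NAMES
    }

    # ---- inference -----------------------------------------------------
    global_comparison = global_metric_comparison(
        {m: global_curves[m]["A"] for m in GLOBAL_METRIC_NAMES},
        {m: global_curves[m]["B"] for m in GLOBAL_METRIC_NAMES},
        grid,
    )
    covariate_cols = [c for c in config.stats.covariates if c in manifest]
    covariates = (
        manifest[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
    )
    order = np.concatenate([idx_a, idx_b])
    perm_tables = []
    stat_seeds = np.random.SeedSequence(config.stats.seed).spawn(
        len(NODAL_METRICS)
    )
    for m, seed in zip(NODAL_METRICS, stat_seeds):
        table = permutation_test_nodal(
            nodal_auc[m][idx_a],
            nodal_auc[m][idx_b],
            covariates=covariates[order] if covariates is not None else None,
            n_perm=config.stats.n_perm,
            seed=int(seed.generate_state(1)[0] % (2**31)),
        )
        table.insert(0, "metric", m)
        table["significant"] = table["p"] < config.stats.alpha
        perm_tables.append(table)
    nodal_permutation = pd.concat(perm_tables, ignore_index=True)
    labels = cleaned[0].roi_labels
    nodal_permutation["label"] = [
        labels[i] for i in nodal_permutation["node"]
    ]

    score_cols = [f"bis_{c}" for c in SCORE_COLUMNS if f"bis_{c}" in manifest]
    behavior_all = behavior_group_b = None
    if score_cols:
        try:
            behavior_all = behavior_correlation_screen(
                nodal_auc,
                manifest[score_cols],
                covariates=covariates,
                node_labels=labels,
            )
        except ValidationError as exc:
            logger.warning("all-subject behavior screen skipped: %s", exc)
        try:
            behavior_group_b = behavior_correlation_screen(
                {m: nodal_auc[m][idx_b] for m in NODAL_METRICS},
                manifest.iloc[idx_b][score_cols].reset_index(drop=True),
                covariates=covariates[idx_b] if covariates is not None else None,
                node_labels=labels,
            )
        except ValidationError as exc:
            logger.warning("group-B behavior screen skipped: %s", exc)

    ce_argmax = {}
    for group, idx in (("A", idx_a), ("B", idx_b)):
        mean_eglo = global_curves["Eglo"][group].mean(axis=0)
        ce_argmax[group] = cost_efficiency(mean_eglo, grid).argmax_sparsity
        logger.info(
            "cost-efficiency argmax, group %s: %.3g", group, ce_argmax[group]
        )

    summary = {
        "n_subjects": {"A": int(idx_a.size), "B": int(idx_b.size)},
        "n_nodes": int(n_nodes),
        "grid": {
            "min": float(grid.values[0]),
            "max": float(grid.values[-1]),
            "step": float(grid.step),
        },
        "per_node_threshold": per_node_threshold(n_nodes),
        "fd_threshold_mm": config.prep.fd_threshold_mm,
        "seeds": {
            "metrics": config.metrics.seed,
            "stats": config.stats.seed,
        },
        "mean_fd": {
            "A": float(qc.loc[idx_a, "mean_fd"].mean()),
            "B": float(qc.loc[idx_b, "mean_fd"].mean()),
        },
        "total_frames_scrubbed": int(qc["n_scrubbed"].sum()),
        "cost_efficiency_argmax": ce_argmax,
        "significant_nodes": {
            m: nodal_permutation.query("metric == @m and significant")[
                "node"
            ].tolist()
            for m in NODAL_METRICS
        },
    }

    report = RunReport(
        qc=qc,
        grid=grid,
        global_curves=global_curves,
        global_comparison=global_comparison,
        nodal_auc=nodal_auc,
        nodal_permutation=nodal_permutation,
        behavior_all=behavior_all,
        behavior_group_b=behavior_group_b,
        cost_efficiency_argmax=ce_argmax,
        summary=summary,
    )
    if write:
        _write_report(report, manifest, outdir)
    return report


def _write_report(report: RunReport, manifest: pd.DataFrame, outdir: Path
                  ) -> None:
    report.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    rows = []
    for m, groups in report.global_curves.items():
        for group, curves in groups.items():
            for s_idx in range(curves.shape[0]):
                for g_idx, s in enumerate(report.grid.values):
                    rows.append(
                        {
                            "metric": m, "group": group, "subject": s_idx,
                            "sparsity": float(s),
                            "value": float(curves[s_idx, g_idx]),
                        }
                    )
    pd.DataFrame(rows).to_csv(outdir / "global_curves.tsv", sep="\t", index=False)
    report.global_comparison.to_csv(
        outdir / "global_comparison.tsv", sep="\t", index=False
    )
    for m, table in report.nodal_auc.items():
        pd.DataFrame(
            table, index=manifest["subject_id"]
        ).to_csv(outdir / f"nodal_auc_{m}.tsv", sep="\t")
    report.nodal_permutation.to_csv(
        outdir / "nodal_permutation.tsv", sep="\t", index=False
    )
    if report.behavior_all is not None:
        report.behavior_all.to_csv(
            outdir / "behavior_correlations_all.tsv", sep="\t", index=False
        )
    if report.behavior_group_b is not None:
        report.behavior_group_b.to_csv(
            outdir / "behavior_correlations_groupB.tsv", sep="\t", index=False
        )
    (outdir / "summary.json").write_text(json.dumps(report.summary, indent=1))
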