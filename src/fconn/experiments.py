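"""Replicate simulation studies: calibration and recovery experiments.

These functions quantify the statistical behaviour of the inference
machinery on data with known ground truth:

* :func:`permutation_type_i_error` — empirical false-positive rate of
  the covariate-adjusted nodal permutation test under the null;
* :func:`exhaustive_permutation_p` — exact permutation p-value by full
  enumeration of relabelings at tiny n (an oracle for the Monte-Carlo
  test);
* :func:`degradation_recovery_rate` — how often a planted nodal
  degradation is detected through the full graph -> time series ->
  network -> AUC -> permutation chain;
* :func:`behavior_recovery_rate` — how often a planted linear
  brain–behavior link of known population correlation is recovered
  with the correct sign.

Recovery experiments run on a scaled-down study (fewer nodes, subjects,
frames and grid points than the full design) so that hundreds of
replicates stay cheap; the generating mechanism is identical to the
full-size one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from fconn.graph_metrics import auc
from fconn.network import SparsityGrid, binarize_at_sparsity, correlation_matrix
from fconn.stats import (
    behavior_correlation_screen,
    permutation_test_nodal,
    residualize,
)
from fconn.synth import (
    degrade_nodes,
    generate_behavioral_scores,
    generate_small_world_graph,
    graph_to_timeseries,
)

__all__ = [
    "ScaledStudy",
    "permutation_type_i_error",
    "exhaustive_permutation_p",
    "degradation_recovery_rate",
    "behavior_recovery_rate",
    "simulate_nodal_auc",
]


@dataclass(frozen=True)
class ScaledStudy:
    """Scaled-down study conditions for replicate experiments."""

    n_nodes: int = 30
    n_per_group: int = 12
    n_timepoints: int = 150
    k: int = 6
    beta: float = 0.1
    edge_weight: float = 0.3
    affected_node: int = 5
    degradation_fraction: float = 0.5
    grid_min: float = 0.12
    grid_max: float = 0.26
    grid_step: float = 0.02


def permutation_type_i_error(
    n_replicates: int = 500,
    n_perm: int = 500,
    n_per_group: int = 18,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the covariate-adjusted permutation test.

    Each replicate draws both groups from one Gaussian (no effect),
    with age- and motion-like covariates correlated with nothing, runs
    the nodal permutation test on a single node and records whether
    p < alpha. Returns the rejection fraction.
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rejections = 0
    n = 2 * n_per_group
    for child in children:
        rng = np.random.default_rng(child)
        values = rng.standard_normal((n, 1))
        covariates = np.column_stack(
            [rng.normal(16, 0.5, n), rng.normal(0.1, 0.01, n)]
        )
        table = permutation_test_nodal(
            values[:n_per_group], values[n_per_group:],
            covariates=covariates, n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        if table["p"].iloc[0] < alpha:
            rejections += 1
    return rejections / n_replicates


def exhaustive_permutation_p(
    a: np.ndarray,
    b: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Exact permutation p by enumerating all relabelings of fixed sizes.

    Counts the relabelings whose |difference of residual group means|
    is at least the observed one (the identity relabeling included), so
    the result is directly comparable with the Monte-Carlo
    (1 + exceedances)/(1 + n_perm) convention.
    """
    a = np.asarray(a, dtype=float).reshape(len(a), -1)
    b = np.asarray(b, dtype=float).reshape(len(b), -1)
    n_a = a.shape[0]
    stacked = np.vstack([a, b])
    resid = residualize(stacked, covariates).ravel()
    n = resid.size
    observed = abs(resid[:n_a].mean() - resid[n_a:].mean())
    count = 0
    total = 0
    for combo in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        stat = abs(resid[mask].mean() - resid[~mask].mean())
        if stat >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def simulate_nodal_auc(
    study: ScaledStudy, seed_sequence: np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """One replicate of the scaled-down study through the full chain.

    Per subject: a Watts–Strogatz true graph (degraded at the planted
    node for group B), Gaussian time series from its covariance, the
    Fisher-z correlation matrix, binarization across the grid, and the
    degree-AUC per node. Returns (auc_a, auc_b), each
    (subjects x nodes).
    """
    grid = SparsityGrid.from_range(study.grid_min, study.grid_max,
                                   study.grid_step)
    n = 2 * study.n_per_group
    streams = seed_sequence.spawn(n)
    aucs = np.zeros((n, study.n_nodes))
    for idx, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        graph = generate_small_world_graph(
            study.n_nodes, study.k, study.beta,
            seed=int(stream.generate_state(1)[0] % (2**31)),
        )
        if idx >= study.n_per_group:
            graph = degrade_nodes(
                graph, (study.affected_node,), study.degradation_fraction, rng
            )
        ts = graph_to_timeseries(
            graph, study.n_timepoints, study.edge_weight, seed=rng
        )
        cm = correlation_matrix(ts)
        degree_curve = np.zeros((len(grid), study.n_nodes))
        for g_idx, s in enumerate(grid.values):
            degree_curve[g_idx] = binarize_at_sparsity(cm, float(s)).degrees()
        aucs[idx] = [
            auc(degree_curve[:, node], grid) for node in range(study.n_nodes)
        ]
    return aucs[: study.n_per_group], aucs[study.n_per_group:]


def degradation_recovery_rate(
    n_replicates: int = 500,
    study: ScaledStudy = ScaledStudy(),
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates detecting the planted nodal degradation.

    Detection = the affected node's degree-AUC permutation p < alpha
    with group B below group A.
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    hits = 0
    for child in children:
        auc_a, auc_b = simulate_nodal_auc(study, child)
        rng = np.random.default_rng(child.spawn(1)[0])
        n = auc_a.shape[0] + auc_b.shape[0]
        covariates = np.column_stack(
            [rng.normal(16, 0.5, n), rng.normal(0.1, 0.01, n)]
        )
        table = permutation_test_nodal(
            auc_a, auc_b, covariates=covariates, n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        row = table.iloc[study.affected_node]
        if row["p"] < alpha and row["diff"] > 0:
            hits += 1
    return hits / n_replicates


def behavior_recovery_rate(
    n_replicates: int = 500,
    study: ScaledStudy = ScaledStudy(),
    population_r: float = 0.6,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates recovering a planted brain–behavior link.

    Each replicate runs the scaled-down study, attaches a behavioral
    score generated from the planted node's degree AUC with noise set
    for the requested population correlation, and screens all
    (node, score) partial correlations controlling age- and motion-like
    covariates. Recovery = the planted node's correlation is positive
    and p < alpha.
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    hits = 0
    for child in children:
        auc_a, auc_b = simulate_nodal_auc(study, child)
        values = np.vstack([auc_a, auc_b])[:, study.affected_node]
        rng = np.random.default_rng(child.spawn(2)[1])
        sd_v = values.std()
        noise_sd = sd_v * np.sqrt(1.0 / population_r**2 - 1.0)
        scores = generate_behavioral_scores(
            values, slope=1.0, noise_sd=noise_sd, seed=rng
        )
        n = values.size
        covariates = np.column_stack(
            [rng.normal(16, 0.5, n), rng.normal(0.1, 0.01, n)]
        )
        table = behavior_correlation_screen(
            {"degree": np.vstack([auc_a, auc_b])},
            pd.DataFrame({"total": scores}),
            covariates=covariates,
        )
        row = table[table["node"] == study.affected_node].iloc[0]
        if row["p"] < alpha and row["r"] > 0:
            hits += 1
    return hits / n_replicates
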