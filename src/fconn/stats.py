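"""Group inference and brain–behavior correlation.

Two inferential routes, mirroring the two levels of the analysis:

* global metrics are compared with pooled two-sample t-tests at every
  sparsity threshold and on each metric's AUC, uncorrected;
* nodal AUCs are compared with covariate-adjusted permutation tests
  (residualize age and mean FD out of the AUCs, then permute group
  labels preserving group sizes);
* behavioral associations are partial correlations (Pearson correlation
  of covariate residuals), screened at a per-node threshold of 1/N.

All permutation machinery is seeded and bit-reproducible; permutation
p-values use the (1 + exceedances) / (1 + n_perm) convention so a
finite-permutation p is never exactly 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from fconn.errors import ComputationError, ValidationError
from fconn.network import SparsityGrid
from fconn.graph_metrics import auc as _auc

__all__ = [
    "TTestResult",
    "pooled_t_test",
    "t_test_from_summary",
    "residualize",
    "partial_correlation",
    "per_node_threshold",
    "permutation_test_nodal",
    "global_metric_comparison",
    "behavior_correlation_screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Student's pooled-variance two-sample t-test, two-sided.

    df = n_a + n_b - 2. Zero pooled variance with equal means gives
    t = 0; zero pooled variance with unequal means is degenerate and
    raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    df = a.size + b.size - 2
    var_pool = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if var_pool == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ComputationError(
            "zero pooled variance with unequal means: t undefined"
        )
    t = diff / np.sqrt(var_pool * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def t_test_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> TTestResult:
    """Pooled two-sample t-test from summary statistics.

    Identical formula to :func:`pooled_t_test`; lets published
    mean ± SD tables be re-checked without raw data.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("standard deviations must be non-negative")
    df = n_a + n_b - 2
    var_pool = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if var_pool == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ComputationError("zero pooled variance with unequal means")
    t = diff / np.sqrt(var_pool * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``y`` (n or n x m) against [intercept | covariates].

    With no covariates this is mean-centering. Raises on a collinear
    covariate matrix.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        design = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValidationError("covariate rows do not align with subjects")
        design = np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError("collinear covariates: design is rank deficient")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates.

    Correlates the OLS residuals of both variables after removing
    [intercept | covariates]; the p-value uses the t transform with
    ``df = n - 2 - n_covariates``. With an empty covariate set this is
    exactly the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    n = x.size
    if covariates is None:
        k = 0
    else:
        cov2 = np.atleast_2d(np.asarray(covariates, dtype=float))
        k = cov2.shape[1] if cov2.shape[0] == n else cov2.shape[0]
    if n <= k + 2:
        raise ValidationError(
            f"need n > n_covariates + 2 (n={n}, covariates={k})"
        )
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ComputationError(
            "zero-variance residuals: partial correlation undefined"
        )
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


def per_node_threshold(n_nodes: int) -> float:
    """Per-node false-positive screening level 1/N (e.g. 1/90 ≈ 0.011)."""
    if n_nodes < 1:
        raise ValidationError("n_nodes must be >= 1")
    return 1.0 / n_nodes


def permutation_test_nodal(
    auc_a: np.ndarray,
    auc_b: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Covariate-adjusted permutation test of group differences per node.

    ``auc_a`` and ``auc_b`` are (subjects x nodes) AUC tables for the
    two groups. Covariates (e.g. age and mean FD, stacked in group
    order) are residualized out of every node's AUC across all subjects
    first; the observed statistic is the absolute difference of group
    means of residuals, compared against ``n_perm`` random relabelings
    that preserve the group sizes. Two-sided by construction;
    p = (1 + #{null >= observed}) / (1 + n_perm).

    Returns a DataFrame with columns ``node`` (0-based), ``diff``
    (signed mean(A) - mean(B) of residuals) and ``p``.
    """
    auc_a = np.atleast_2d(np.asarray(auc_a, dtype=float))
    auc_b = np.atleast_2d(np.asarray(auc_b, dtype=float))
    if auc_a.shape[1] != auc_b.shape[1]:
        raise ValidationError("groups have different node counts")
    n_a, n_b = auc_a.shape[0], auc_b.shape[0]
    if min(n_a, n_b) < 3:
        raise ValidationError("each group needs at least 3 subjects")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very small; p-values will be coarse",
            stacklevel=2,
        )
    stacked = np.vstack([auc_a, auc_b])
    resid = residualize(stacked, covariates)
    n = n_a + n_b
    contrast = np.concatenate([np.full(n_a, 1.0 / n_a), np.full(n_b, -1.0 / n_b)])
    observed = contrast @ resid
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    # a shuffled contrast vector puts weight 1/n_a on a random size-n_a
    # subset: a random relabeling with the original group sizes
    null = np.abs(contrast[perms] @ resid)
    # ties with the observed statistic count as exceedances (conservative);
    # the tolerance absorbs summation-order float noise in exact ties
    thresh = np.abs(observed) - 1e-12 * np.maximum(1.0, np.abs(observed))
    exceed = (null >= thresh[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {"node": np.arange(resid.shape[1]), "diff": observed, "p": p}
    )


def global_metric_comparison(
    curves_a: dict[str, np.ndarray],
    curves_b: dict[str, np.ndarray],
    grid: SparsityGrid,
) -> pd.DataFrame:
    """Pooled t-tests on global metric curves at every sparsity and on AUCs.

    ``curves_a[metric]`` is a (subjects x grid) array for group A, same
    for B. Returns one row per (metric, sparsity) plus one per
    (metric, "AUC"), uncorrected p-values throughout.
    """
    rows = []
    for metric in curves_a:
        if metric not in curves_b:
            raise ValidationError(f"metric {metric!r} missing from group B")
        a = np.atleast_2d(np.asarray(curves_a[metric], dtype=float))
        b = np.atleast_2d(np.asarray(curves_b[metric], dtype=float))
        if a.shape[1] != len(grid) or b.shape[1] != len(grid):
            raise ValidationError(
                f"curves for {metric!r} do not match the {len(grid)}-point grid"
            )
        for idx, s in enumerate(grid.values):
            res = pooled_t_test(a[:, idx], b[:, idx])
            rows.append(
                {
                    "metric": metric, "sparsity": float(s),
                    "mean_a": a[:, idx].mean(), "sd_a": a[:, idx].std(ddof=1),
                    "mean_b": b[:, idx].mean(), "sd_b": b[:, idx].std(ddof=1),
                    "t": res.t, "df": res.df, "p": res.p,
                }
            )
        auc_a = np.array([_auc(row, grid) for row in a])
        auc_b = np.array([_auc(row, grid) for row in b])
        res = pooled_t_test(auc_a, auc_b)
        rows.append(
            {
                "metric": metric, "sparsity": "AUC",
                "mean_a": auc_a.mean(), "sd_a": auc_a.std(ddof=1),
                "mean_b": auc_b.mean(), "sd_b": auc_b.std(ddof=1),
                "t": res.t, "df": res.df, "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def behavior_correlation_screen(
    nodal_aucs: dict[str, np.ndarray],
    behavior_scores: pd.DataFrame,
    covariates: np.ndarray | None = None,
    node_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Partial correlations of every (node, nodal metric, score) triple.

    ``nodal_aucs[metric]`` is a (subjects x nodes) AUC table;
    ``behavior_scores`` has one column per score, aligned to the same
    subjects. Subjects with missing scores are dropped (count logged).
    Each row is flagged at the per-node threshold 1/N
    (``significant_per_node``) and at uncorrected 0.05
    (``significant_unc``).
    """
    metrics = list(nodal_aucs)
    n_nodes = np.atleast_2d(nodal_aucs[metrics[0]]).shape[1]
    threshold = per_node_threshold(n_nodes)
    rows = []
    for score_name in behavior_scores.columns:
        scores = np.asarray(behavior_scores[score_name], dtype=float)
        valid = np.isfinite(scores)
        dropped = int((~valid).sum())
        if dropped:
            logger.info(
                "dropping %d subject(s) with missing %s", dropped, score_name
            )
        if scores[valid].std() == 0:
            raise ComputationError(
                f"behavioral score {score_name!r} is constant: "
                "correlation undefined"
            )
        cov = None
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != scores.size:
                cov = cov.T
            cov = cov[valid]
        for metric in metrics:
            table = np.atleast_2d(np.asarray(nodal_aucs[metric], dtype=float))
            for node in range(table.shape[1]):
                r, p = partial_correlation(table[valid, node], scores[valid], cov)
                rows.append(
                    {
                        "metric": metric,
                        "node": node,
                        "label": node_labels[node] if node_labels else f"ROI{node + 1}",
                        "score": score_name,
                        "r": r,
                        "p": p,
                        "significant_per_node": p < threshold,
                        "significant_unc": p < 0.05,
                    }
                )
    return pd.DataFrame(rows)
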