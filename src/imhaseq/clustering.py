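"""Case-only hierarchical clustering of expression profiles.

Affected samples are clustered on their variance-stabilized expression:
Euclidean distances, Ward's revised agglomeration (the squared-distance
Lance-Williams formulation, heights reported on the original distance
scale — equivalent to clustering the raw profiles with Ward's criterion),
a within-cluster sum-of-squared-error (SSE) curve to choose the number of
clusters, and per-gene Welch t tests between the two primary clusters at
FDR <= 0.05 with log2FC confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


def euclidean_distance(vst_cases: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Euclidean distances over genes (rows of input)."""
    if vst_cases.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = vst_cases.to_numpy(dtype=float).T
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=vst_cases.columns, columns=vst_cases.columns)


def ward_linkage(dist: pd.DataFrame) -> np.ndarray:
    """Ward's revised agglomeration from a Euclidean distance matrix.

    Uses the Lance-Williams update on squared distances with merge heights
    reported on the original distance scale (d, not d^2), matching Ward
    clustering of the underlying observations.
    """
    D = dist.to_numpy(dtype=float)
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("invalid distance matrix")
    return linkage(squareform(D, checks=False), method="ward")


@dataclass
class CaseClusterResult:
    linkage: np.ndarray
    sse_curve: pd.Series  # k -> within-cluster SSE
    k: int
    assignments: pd.Series  # sample -> cluster (1..k)


def sse_curve(
    vst_cases: pd.DataFrame, Z: np.ndarray, k_max: int = 8, k: int | None = None
) -> CaseClusterResult:
    """Within-cluster SSE for k = 1..k_max cuts of the tree.

    SSE(k) = sum over clusters of squared distances to the cluster
    centroid.  The default k maximizes the drop ratio SSE(k-1)/SSE(k) for
    k >= 2 (the elbow); pass ``k`` to override.
    """
    X = vst_cases.to_numpy(dtype=float).T
    n = X.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be < number of samples")
    curve = {}
    assignments = {}
    for kk in range(1, k_max + 1):
        lab = fcluster(Z, t=kk, criterion="maxclust")
        sse = 0.0
        for c in np.unique(lab):
            sub = X[lab == c]
            sse += ((sub - sub.mean(axis=0)) ** 2).sum()
        curve[kk] = sse
        assignments[kk] = lab
    curve = pd.Series(curve, name="sse")
    if k is None:
        ratios = {
            kk: (curve[kk - 1] / curve[kk] if curve[kk] > 0 else np.inf)
            for kk in range(2, k_max + 1)
        }
        k = max(ratios, key=ratios.get)
    labels = pd.Series(assignments[k], index=vst_cases.columns, name="cluster")
    log.info("SSE curve %s; chose k=%d", dict(curve.round(1)), k)
    return CaseClusterResult(linkage=Z, sse_curve=curve, k=k, assignments=labels)


def cluster_gene_tests(
    expr: pd.DataFrame, assignments: pd.Series, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-gene Welch t tests between exactly two clusters.

    Returns per-gene t, p, BH-adjusted p, significance at ``fdr``, the
    cluster-2-vs-cluster-1 expression difference (log2FC on VST input) and
    its 95% Welch interval.
    """
    assignments = assignments.loc[expr.columns]
    clusters = sorted(assignments.unique())
    if len(clusters) != 2:
        raise ValueError(
            f"expected exactly 2 clusters, got {len(clusters)}; "
            "run pairwise comparisons for more"
        )
    g1 = expr.loc[:, (assignments == clusters[0]).to_numpy()]
    g2 = expr.loc[:, (assignments == clusters[1]).to_numpy()]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("each cluster needs >= 2 samples")
    t, p = stats.ttest_ind(
        g2.to_numpy(), g1.to_numpy(), axis=1, equal_var=False
    )
    m2, m1 = g2.mean(axis=1).to_numpy(), g1.mean(axis=1).to_numpy()
    v2, v1 = g2.var(axis=1, ddof=1).to_numpy(), g1.var(axis=1, ddof=1).to_numpy()
    n2, n1 = g2.shape[1], g1.shape[1]
    se2 = v2 / n2 + v1 / n1
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / ((v2 / n2) ** 2 / (n2 - 1) + (v1 / n1) ** 2 / (n1 - 1))
    tcrit = stats.t.ppf(0.975, np.where(np.isfinite(df), df, n1 + n2 - 2))
    half = tcrit * np.sqrt(se2)
    diff = m2 - m1
    res = pd.DataFrame(
        {
            "t": t,
            "p": np.where(np.isnan(p), 1.0, p),
            "log2fc": diff,
            "ci_low": diff - half,
            "ci_high": diff + half,
        },
        index=expr.index,
    )
    res["padj"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["padj"] <= fdr
    return res
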