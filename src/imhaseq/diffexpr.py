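"""Differential expression: prefilter, normalization, NB Wald test, the
three-criterion DEG filter, VST/TPM transforms, PCA outlier screening, and
housekeeping-gene selection.

The test is deliberately a simple negative-binomial Wald test with
method-of-moments dispersion on median-of-ratios-normalized counts — not a
reimplementation of shrinkage machinery.  Genes are called differentially
expressed when all three hold: BH-adjusted p <= 0.05, |log2FC| >= 2, and
baseMean (mean normalized count over all samples) >= 10, with a count
prefilter of >= 10 reads in >= 5 samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import CountMatrix

log = logging.getLogger(__name__)


def prefilter(
    cm: CountMatrix, min_count: int = 10, min_samples: int = 5
) -> CountMatrix:
    """Keep genes with count >= min_count in at least min_samples samples."""
    keep = (cm.counts >= min_count).sum(axis=1) >= min_samples
    lengths = cm.gene_lengths[keep] if cm.gene_lengths is not None else None
    log.info(
        "prefilter(count>=%d in >=%d samples): kept %d / %d genes",
        min_count, min_samples, int(keep.sum()), cm.shape[0],
    )
    return CountMatrix(cm.counts.loc[keep], gene_lengths=lengths)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    factor_s = median over all-positive genes of count_gs / geomean_g.
    """
    counts = cm.counts.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "a pseudo-reference fallback is required for such data"
        )
    ref = counts[allpos]
    geo = np.exp(np.log(ref).mean(axis=1))
    ratios = ref / geo[:, None]
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.log(sf).mean())
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    return cm.counts / sf


def nb_test(
    cm: CountMatrix, labels: pd.Series, sf: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene case-vs-control NB Wald test on normalized counts.

    Dispersion alpha is a per-gene method-of-moments estimate pooled over
    the two groups (variance = mu + alpha*mu^2, clipped at 0); log2FC uses
    a pseudo-count c = 0.5 / median size factor; the Wald SE comes from the
    delta method on log2 of the group means.  All-zero genes report
    log2fc = 0, p = 1.
    """
    labels = labels.reindex(cm.sample_ids)
    groups = labels.unique()
    if set(groups) != {"case", "control"}:
        raise ValueError(f"labels must be 'case'/'control', got {sorted(groups)}")
    if sf is None:
        sf = size_factors(cm)
    norm = normalized_counts(cm, sf)
    case = norm.loc[:, (labels == "case").to_numpy()]
    ctrl = norm.loc[:, (labels == "control").to_numpy()]
    n1, n0 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >= 2 samples")

    mu1 = case.mean(axis=1).to_numpy()
    mu0 = ctrl.mean(axis=1).to_numpy()
    v1 = case.var(axis=1, ddof=1).to_numpy()
    v0 = ctrl.var(axis=1, ddof=1).to_numpy()
    # pooled MoM dispersion: average of per-group (v - mu)/mu^2, clipped
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - mu1) / mu1**2
        a0 = (v0 - mu0) / mu0**2
    stacked = np.stack([a1, a0])
    all_nan = np.isnan(stacked).all(axis=0)
    stacked[:, all_nan] = 0.0  # all-zero genes: dispersion irrelevant
    alpha = np.nanmean(stacked, axis=0)
    alpha = np.clip(np.nan_to_num(alpha), 0.0, None)

    c = 0.5 / float(np.median(sf))
    l2fc = np.log2((mu1 + c) / (mu0 + c))
    var_mean1 = (mu1 + alpha * mu1**2) / n1
    var_mean0 = (mu0 + alpha * mu0**2) / n0
    se = np.sqrt(
        var_mean1 / (mu1 + c) ** 2 + var_mean0 / (mu0 + c) ** 2
    ) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = l2fc / se
    p = 2 * stats.norm.sf(np.abs(z))
    zero = (mu1 == 0) & (mu0 == 0)
    l2fc[zero] = 0.0
    p[np.isnan(p) | zero] = 1.0

    res = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2fc": l2fc,
            "se": se,
            "p": p,
        },
        index=cm.counts.index,
    )
    res["padj"] = bh_adjust(res["p"].to_numpy())
    return res


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(results: pd.DataFrame, config: PipelineConfig | None = None):
    """Apply the three-criterion DEG filter; returns (over, under) tables.

    Flags pass_padj, pass_l2fc, pass_basemean and is_deg are added to a
    copy of the results table, sorted by descending |log2FC|.
    """
    cfg = config or PipelineConfig()
    res = results.copy()
    res["pass_padj"] = res["padj"] <= cfg.deg_padj
    res["pass_l2fc"] = res["log2fc"].abs() >= cfg.deg_abs_l2fc
    res["pass_basemean"] = res["baseMean"] >= cfg.deg_basemean
    res["is_deg"] = res.pass_padj & res.pass_l2fc & res.pass_basemean
    degs = res[res.is_deg].sort_values("log2fc", ascending=False)
    over = degs[degs.log2fc > 0]
    under = degs[degs.log2fc < 0]
    log.info(
        "DEG filter (padj<=%g, |l2fc|>=%g, baseMean>=%g): %d over, %d under "
        "of %d genes",
        cfg.deg_padj, cfg.deg_abs_l2fc, cfg.deg_basemean,
        len(over), len(under), len(res),
    )
    return over, under, res


def fold_change(log2fc: float) -> float:
    """Linear fold 2^log2fc, rounded to the nearest integer when >= 10
    (reporting convention for large folds)."""
    fold = 2.0 ** log2fc
    if abs(fold) >= 10:
        return float(round(fold))
    return fold


def vst(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """Simple variance-stabilizing transform: log2(count/size_factor + 1)."""
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(cm.counts / sf + 1.0)


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per
    sample."""
    if cm.gene_lengths is None:
        raise ValueError("gene lengths are required for TPM")
    rate = cm.counts.div(cm.gene_lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def pca_outliers(
    vst_matrix: pd.DataFrame, n_components: int = 3, cutoff_sd: float = 4.0
) -> pd.DataFrame:
    """Flag samples far from the centroid in leading principal components.

    Scores come from the SVD of the sample x gene matrix (genes centered);
    a sample is flagged when its Euclidean distance from the component-space
    centroid exceeds ``cutoff_sd`` robust standard deviations
    (1.4826 x MAD) of the cohort's distances.  Flags are advisory.
    """
    X = vst_matrix.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 3:
        raise ValueError("PCA outlier screen needs >= 3 samples")
    Xc = X - X.mean(axis=0)
    n_components = min(n_components, min(Xc.shape) - 1)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    d = np.linalg.norm(scores - scores.mean(axis=0), axis=1)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    robust_sd = 1.4826 * mad if mad > 0 else d.std() or 1.0
    flagged = d > med + cutoff_sd * robust_sd
    out = pd.DataFrame(
        {"distance": d, "robust_z": (d - med) / robust_sd, "outlier": flagged},
        index=vst_matrix.columns,
    )
    if flagged.any():
        log.info("PCA outliers flagged: %s", list(out.index[flagged]))
    return out


def select_housekeeping(
    results: pd.DataFrame,
    vst_matrix: pd.DataFrame,
    basemean_range=(500.0, 3000.0),
    max_abs_l2fc: float = 0.1,
) -> pd.DataFrame:
    """Rank housekeeping candidates: moderately expressed genes (baseMean in
    [500, 3000]) with |log2FC| < 0.1, ordered by ascending coefficient of
    variation of their VST values."""
    lo, hi = basemean_range
    ok = (
        (results["baseMean"] >= lo)
        & (results["baseMean"] <= hi)
        & (results["log2fc"].abs() < max_abs_l2fc)
    )
    genes = results.index[ok]
    sub = vst_matrix.loc[genes]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    out = pd.DataFrame(
        {
            "baseMean": results.loc[genes, "baseMean"],
            "log2fc": results.loc[genes, "log2fc"],
            "cv": cv,
        }
    )
    return out.sort_values("cv")
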