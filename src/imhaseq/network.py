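"""Weighted correlation network analysis.

Builds an unsigned adjacency a_ij = |cor(x_i, x_j)|^beta from
variance-stabilized expression, derives the topological overlap matrix
(TOM), detects modules by average-linkage clustering of 1 - TOM with a
static tree cut, summarizes each module by its eigengene (first singular
vector of the standardized module submatrix), merges modules whose
eigengenes correlate above a cutoff, and relates modules and genes to
CBC-derived traits:

* module-trait: Pearson r between eigengene and trait, p from the
  t-distribution with n - 2 df;
* gene significance (GS): cor(gene, trait); module membership (MM):
  cor(gene, own module eigengene);
* gene selection at GS p <= 0.05, MM p <= 0.05, MM >= 0;
* hypergeometric overrepresentation of selected genes in annotated sets;
* one-way ANOVA + Tukey HSD of expression across clinical groupings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

UNASSIGNED = 0  # module label for genes in no module


def _drop_zero_variance(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=1)
    bad = sd == 0
    if bad.any():
        log.warning("removing %d zero-variance genes", int(bad.sum()))
        expr = expr.loc[~bad]
    return expr


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |pearson|^beta over genes (rows of expr)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    expr = _drop_zero_variance(expr)
    r = np.corrcoef(expr.to_numpy(dtype=float))
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def pick_soft_power(
    expr: pd.DataFrame,
    candidates=range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest power whose scale-free topology fit reaches r2_target.

    The fit index is the signed R^2 (-sign(slope) * R^2) of the regression
    of log10 frequency on log10 mean connectivity over >= n_bins
    connectivity bins.  Falls back to the candidate with maximal fit.
    """
    if expr.shape[1] < 8:
        raise ValueError("need >= 8 samples to estimate soft power")
    expr = _drop_zero_variance(expr)
    absr = np.abs(np.corrcoef(expr.to_numpy(dtype=float)))
    np.fill_diagonal(absr, 0.0)
    best_beta, best_fit = None, -np.inf
    for beta in candidates:
        k = (absr**beta).sum(axis=1)
        fit = _scale_free_fit(k, n_bins)
        if fit >= r2_target:
            log.info("soft power %d reaches scale-free fit %.3f", beta, fit)
            return int(beta)
        if fit > best_fit:
            best_beta, best_fit = int(beta), fit
    log.info(
        "no candidate reached fit %.2f; using beta=%d (fit %.3f)",
        r2_target, best_beta, best_fit,
    )
    return best_beta


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if len(k) < n_bins:
        return -np.inf
    edges = np.linspace(k.min(), k.max(), n_bins + 1)  # equal-width bins
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    logk, logf = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        logk.append(np.log10(k[sel].mean()))
        logf.append(np.log10(sel.mean()))
    if len(logk) < 3:
        return -np.inf
    slope, _, r, _, _ = stats.linregress(logk, logf)
    return -np.sign(slope) * r**2


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu * a_uj and k_i = sum_{u != i} a_iu;
    TOM_ii = 1.
    """
    A = adj.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any() or (A > 1).any():
        raise ValueError("adjacency values must lie in [0, 1]")
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0  # L_ij includes u=i,j terms only via zeroed diagonal: exact
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A0) / (kmin + 1.0 - A0)
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def detect_modules(
    tom_matrix: pd.DataFrame, min_module_size: int = 30, cut_height: float = 0.99
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` become module 0
    (unassigned); surviving clusters are renumbered 1..m by decreasing
    size.
    """
    D = 1.0 - tom_matrix.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom_matrix.index, name="module")
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    remap = {old: new for new, old in enumerate(
        sorted(keep, key=lambda c: -sizes[c]), start=1)}
    return labels.map(lambda c: remap.get(c, UNASSIGNED)).rename("module")


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Module x sample eigengenes.

    Each module's eigengene is the first right singular vector of its
    per-gene z-scored submatrix (unit norm across samples), with the sign
    chosen so the mean correlation with member genes is >= 0.  Module 0 is
    excluded; a single-gene module's eigengene is that gene's normalized
    z-score.
    """
    out = {}
    Xall = expr.to_numpy(dtype=float)
    z = (Xall - Xall.mean(axis=1, keepdims=True))
    sd = Xall.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    for mod in sorted(labels.unique()):
        if mod == UNASSIGNED:
            continue
        sub = zdf.loc[labels.index[labels == mod]].to_numpy()
        _, _, Vt = np.linalg.svd(sub, full_matrices=False)
        eig = Vt[0]
        corr_sign = np.sign((sub @ eig).mean())
        if corr_sign < 0:
            eig = -eig
        out[mod] = eig
    eg = pd.DataFrame(out, index=expr.columns).T
    eg.index.name = "module"
    return eg


@dataclass
class ModuleSet:
    """Result of module detection and merging."""

    soft_power: int
    labels: pd.Series  # gene -> module (0 = unassigned)
    eigengenes: pd.DataFrame  # module x sample
    merge_history: list = field(default_factory=list)


def merge_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    merge_cor: float = 0.30,
    soft_power: int = 1,
    merge_on: str = "dissimilarity",
) -> ModuleSet:
    """Greedily merge the most-correlated eigengene pair, recomputing
    eigengenes after each merge.

    With ``merge_on="dissimilarity"`` (default), modules merge while the
    eigengene dissimilarity 1 - r is below ``merge_cor`` (i.e. r > 0.70
    at the 0.30 cutoff) — the semantics of the standard eigengene
    merge-height parameter.  ``merge_on="correlation"`` merges while
    r > ``merge_cor`` directly; under case/control cohort structure that
    reading collapses distinct trait-linked modules, since every
    group-responsive eigengene correlates well above 0.30.
    """
    if merge_on not in ("dissimilarity", "correlation"):
        raise ValueError("merge_on must be 'dissimilarity' or 'correlation'")
    cor_cut = (1.0 - merge_cor) if merge_on == "dissimilarity" else merge_cor
    labels = labels.copy()
    history = []
    while True:
        eg = module_eigengene(expr, labels)
        mods = list(eg.index)
        if len(mods) < 2:
            break
        C = np.corrcoef(eg.to_numpy())
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= cor_cut:
            break
        a, b = mods[i], mods[j]
        keep, drop = min(a, b), max(a, b)
        labels[labels == drop] = keep
        history.append((keep, drop, float(C[i, j])))
        log.info("merged module %d into %d (r=%.3f)", drop, keep, C[i, j])
    eg = module_eigengene(expr, labels)
    return ModuleSet(
        soft_power=soft_power, labels=labels, eigengenes=eg, merge_history=history
    )


def _cor_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r from the t-distribution, n-2 df."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def module_trait(eigengenes: pd.DataFrame, traits: pd.DataFrame):
    """Pearson correlation of each eigengene with each trait column.

    Returns (r, p) DataFrames, module x trait; constant traits give NaN.
    """
    traits = traits.loc[eigengenes.columns]
    n = traits.shape[0]
    r = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        if np.std(t) == 0:
            r[trait] = np.nan
            continue
        for mod in eigengenes.index:
            r.loc[mod, trait] = np.corrcoef(eigengenes.loc[mod], t)[0, 1]
    p = pd.DataFrame(
        _cor_p(r.to_numpy(dtype=float), n), index=r.index, columns=r.columns
    )
    p[r.isna()] = np.nan
    return r, p


def gene_stats(
    expr: pd.DataFrame,
    eigengenes: pd.DataFrame,
    labels: pd.Series,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-gene gene significance and module membership with p-values."""
    trait = trait.loc[expr.columns].to_numpy(dtype=float)
    n = len(trait)
    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    tc = trait - trait.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(tc)
    denom[denom == 0] = np.nan
    gs = (Xc @ tc) / denom
    mm = np.full(len(expr), np.nan)
    for mod in eigengenes.index:
        sel = (labels == mod).to_numpy()
        if not sel.any():
            continue
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        ec = e - e.mean()
        d = np.linalg.norm(Xc[sel], axis=1) * np.linalg.norm(ec)
        d[d == 0] = np.nan
        mm[sel] = (Xc[sel] @ ec) / d
    out = pd.DataFrame(
        {
            "module": labels,
            "gs": gs,
            "gs_p": _cor_p(np.nan_to_num(gs), n),
            "mm": mm,
            "mm_p": np.where(np.isnan(mm), np.nan, _cor_p(np.nan_to_num(mm), n)),
        },
        index=expr.index,
    )
    return out


def select_module_genes(
    stats_df: pd.DataFrame, gs_p: float = 0.05, mm_p: float = 0.05
) -> list:
    """Genes with GS p <= gs_p, MM p <= mm_p, and MM >= 0."""
    ok = (
        (stats_df["gs_p"] <= gs_p)
        & (stats_df["mm_p"] <= mm_p)
        & (stats_df["mm"] >= 0)
    )
    return list(stats_df.index[ok.fillna(False)])


def overrepresentation(selected, collection, universe) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail overrepresentation of the
    selected genes in each annotated set, BH-adjusted across sets."""
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    M, N = len(universe), len(selected)
    rows = []
    for name in collection.names():
        members = set(collection.members(name)) & universe
        if not members:
            log.warning("set %r disjoint from universe; skipped", name)
            continue
        k = len(members & selected)
        K = len(members)
        p = stats.hypergeom.sf(k - 1, M, K, N)
        # Haldane-corrected odds ratio of the 2x2 overlap table
        a, b = k, K - k
        c, d = N - k, M - K - (N - k)
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {"set": name, "set_size": K, "overlap": k, "odds_ratio": orat, "p": p}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def group_anova_tukey(
    tpm_matrix: pd.DataFrame, genes, groupings: pd.Series, alpha: float = 0.05
):
    """Per-gene one-way ANOVA across sample groupings, with Tukey HSD
    pairwise p-values for genes whose ANOVA p <= alpha.

    Returns (anova, tukey): per-gene F/p table, and a tidy frame of
    pairwise group comparisons for the significant genes.
    """
    groupings = groupings.loc[tpm_matrix.columns]
    names = [g for g in pd.unique(groupings) if pd.notna(g)]
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    cols = {g: groupings.index[groupings == g] for g in names}
    for g, idx in cols.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has < 2 samples")
    arows, trows = [], []
    for gene in genes:
        samples = [tpm_matrix.loc[gene, idx].to_numpy(dtype=float) for idx in cols.values()]
        F, p = stats.f_oneway(*samples)
        arows.append({"gene": gene, "F": F, "p": p})
        if p <= alpha:
            res = stats.tukey_hsd(*samples)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    trows.append(
                        {
                            "gene": gene,
                            "group_a": names[i],
                            "group_b": names[j],
                            "p": res.pvalue[i, j],
                            "significant": res.pvalue[i, j] <= alpha,
                        }
                    )
    anova = pd.DataFrame(arows).set_index("gene")
    tukey = pd.DataFrame(trows, columns=["gene", "group_a", "group_b", "p", "significant"])
    return anova, tukey
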