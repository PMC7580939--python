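"""Gene-set enrichment: pre-ranked running-sum scoring with a permutation
null, single-sample enrichment on TPM, and pathway-similarity edge export.

The pre-ranked statistic is the weighted Kolmogorov-Smirnov running sum:
walking down the ranked list, set members increment the sum by
|score|^weight normalized over members, non-members decrement by
1/(N - N_hits); the enrichment score (ES) is the extremum.  Significance
comes from random equal-size gene-label draws, with the normalized ES
(NES) scaled by the mean |null ES| of matching sign, and BH adjustment
across sets (significant at FDR <= 0.1).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust
from .io import GeneSetCollection

log = logging.getLogger(__name__)


def _sort_ranked(ranked: pd.Series) -> pd.Series:
    """Descending by score; ties broken by gene id for determinism."""
    if ranked.index.duplicated().any():
        raise ValueError("duplicate genes in ranked list")
    df = pd.DataFrame({"score": ranked})
    df = df.sort_values(
        ["score"], ascending=False, kind="mergesort"
    ).sort_index(kind="mergesort").sort_values(
        "score", ascending=False, kind="mergesort"
    )
    return df["score"]


def _es_from_positions(absw_pow, positions, n_total):
    """ES and extremum index given sorted 0-based hit positions.

    positions: (n_draws, k) array, ascending within each row.
    Returns (es, at_hit_index) arrays of length n_draws.
    """
    pos = np.atleast_2d(positions)
    ndraw, k = pos.shape
    w = absw_pow[pos]
    denom = w.sum(axis=1, keepdims=True)
    # uniform hit weights if all scores in the set are zero
    W = np.where(denom > 0, np.cumsum(w, axis=1) / np.where(denom == 0, 1, denom),
                 (np.arange(1, k + 1) / k)[None, :])
    n_miss = n_total - k
    miss_step = (pos - np.arange(k)[None, :]) / n_miss if n_miss > 0 else np.zeros_like(pos, dtype=float)
    after = W - miss_step            # running sum just after each hit
    Wprev = np.concatenate([np.zeros((ndraw, 1)), W[:, :-1]], axis=1)
    before = Wprev - miss_step       # running sum just before each hit
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    es = np.where(hi >= -lo, hi, lo)
    idx = np.where(hi >= -lo, after.argmax(axis=1), before.argmin(axis=1))
    return es, idx


def preranked_es(ranked: pd.Series, members, weight: float = 1.0):
    """Weighted KS enrichment score for one gene set.

    Parameters
    ----------
    ranked
        gene -> score, any order; sorted descending internally.
    members
        gene ids of the set; genes absent from the list are ignored.
    weight
        Exponent on |score| for hit increments; 0 recovers the classical
        unweighted KS statistic.

    Returns
    -------
    (es, running_sum, leading_edge) where running_sum is a pd.Series over
    the ranked list and leading_edge the member genes at or before the
    extremum (at or after, for negative ES).
    """
    ranked = _sort_ranked(ranked)
    genes = ranked.index
    hits = genes.isin(set(members))
    k = int(hits.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    n = len(genes)
    if k == n:
        log.warning("gene set covers the entire ranked list (degenerate ES)")
    absw = np.abs(ranked.to_numpy()) ** weight
    positions = np.flatnonzero(hits)
    es_arr, idx_arr = _es_from_positions(absw, positions[None, :], n)
    es, at = float(es_arr[0]), int(idx_arr[0])

    # full running sum, for plotting/inspection
    denom = absw[positions].sum()
    incr = np.where(
        hits,
        (absw / denom) if denom > 0 else (1.0 / k),
        -(1.0 / (n - k)) if n > k else 0.0,
    )
    running = pd.Series(np.cumsum(incr), index=genes, name="running_sum")

    if es >= 0:
        cut = positions[at]
        leading = [g for g in genes[: cut + 1] if g in set(members)]
    else:
        cut = positions[at]
        leading = [g for g in genes[cut:] if g in set(members)]
    return es, running, leading


def preranked_significance(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Permutation significance for every set in the collection.

    Null ES per set from ``n_perm`` random same-size gene draws; the
    permutation p is two-one-sided with the +1 correction (so always
    >= 1/(n_perm+1)); FDR is BH across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = _sort_ranked(ranked)
    n = len(ranked)
    absw = np.abs(ranked.to_numpy()) ** weight
    rng = np.random.default_rng(seed)
    rows = []
    gene_set_index = set(ranked.index)
    null_cache: dict[int, np.ndarray] = {}
    for name in collection.names():
        members = [g for g in collection.members(name) if g in gene_set_index]
        k = len(members)
        if k == 0:
            log.warning("set %r skipped: empty intersection with ranked list", name)
            continue
        es, _, leading = preranked_es(ranked, members, weight)
        if k not in null_cache:
            draws = np.stack(
                [rng.choice(n, size=k, replace=False) for _ in range(n_perm)]
            )
            draws.sort(axis=1)
            null_cache[k] = _es_from_positions(absw, draws, n)[0]
        null = null_cache[k]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        scale = np.abs(same).mean() if len(same) else np.abs(null).mean()
        nes = es / scale if scale > 0 else 0.0
        if es >= 0:
            one_sided = (1 + int((null >= es).sum())) / (1 + n_perm)
        else:
            one_sided = (1 + int((null <= es).sum())) / (1 + n_perm)
        p = min(1.0, 2 * one_sided)
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(leading),
            }
        )
    res = pd.DataFrame(rows).set_index("set")
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["fdr"] <= fdr_threshold
    return res


def ssgsea(
    tpm_matrix: pd.DataFrame,
    collection: GeneSetCollection,
    exponent: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample enrichment scores (set x sample).

    Within each sample, genes are ordered by descending expression (ties
    broken by gene id); position i from the top gets rank N - i, and the
    score is the sum over the list of the difference between the
    rank^exponent-weighted ECDF of set members and the unweighted ECDF of
    non-members.  Optional min-max normalization across the whole matrix.
    """
    colsums = tpm_matrix.sum(axis=0)
    if not np.allclose(colsums, 1e6, rtol=1e-6):
        raise ValueError("ssgsea expects TPM input (columns summing to 1e6)")
    n = tpm_matrix.shape[0]
    scores = {}
    member_masks = {}
    for name in collection.names():
        members = set(collection.members(name)) & set(tpm_matrix.index)
        if len(members) < 2:
            log.warning("set %r skipped in ssGSEA: < 2 genes after intersection", name)
            continue
        member_masks[name] = members
    for sample in tpm_matrix.columns:
        expr = tpm_matrix[sample]
        order = expr.to_frame("e").sort_values(
            "e", ascending=False, kind="mergesort"
        )
        order = order.sort_index(kind="mergesort").sort_values(
            "e", ascending=False, kind="mergesort"
        )
        genes = order.index
        ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets N
        rw = ranks**exponent
        col = {}
        for name, members in member_masks.items():
            hit = genes.isin(members)
            k = int(hit.sum())
            p_in = np.cumsum(np.where(hit, rw, 0.0))
            p_in /= p_in[-1]
            p_out = np.cumsum(~hit) / (n - k)
            col[name] = float((p_in - p_out).sum())
        scores[sample] = col
    out = pd.DataFrame(scores)
    if normalize:
        rng_ = out.to_numpy().max() - out.to_numpy().min()
        if rng_ > 0:
            out = (out - out.to_numpy().min()) / rng_
    return out


def pathway_similarity_edges(
    set_names,
    collection: GeneSetCollection,
    cutoff: float = 0.375,
    min_neighbors: int = 2,
) -> pd.DataFrame:
    """Edges between similar pathways for enrichment-map style export.

    Similarity is the mean of the Jaccard index and the overlap
    coefficient between member sets; edges with similarity >= cutoff are
    kept, then nodes with fewer than ``min_neighbors`` neighbors (and
    their edges) are dropped in a single pass.
    """
    names = list(set_names)
    edges = []
    for a, b in combinations(names, 2):
        sa, sb = set(collection.members(a)), set(collection.members(b))
        inter = len(sa & sb)
        if inter == 0:
            continue
        jac = inter / len(sa | sb)
        ovl = inter / min(len(sa), len(sb))
        sim = (jac + ovl) / 2
        if sim >= cutoff:
            edges.append({"set_a": a, "set_b": b, "similarity": sim})
    df = pd.DataFrame(edges, columns=["set_a", "set_b", "similarity"])
    if df.empty or min_neighbors <= 0:
        return df
    degree = pd.concat([df.set_a, df.set_b]).value_counts()
    keep = set(degree.index[degree >= min_neighbors])
    return df[df.set_a.isin(keep) & df.set_b.isin(keep)].reset_index(drop=True)
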