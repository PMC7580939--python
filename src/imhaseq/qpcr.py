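"""Relative qPCR quantification by the ddCT method.

For each dog, dCT = mean Ct(target) - mean Ct(housekeeping) over
replicates; ddCT = mean_case(dCT) - mean_control(dCT); assuming perfect
doubling per cycle, log2FC = -ddCT and fold = 2^(-ddCT).  The 95% CI is a
Welch t interval on the two-group dCT difference.  Replicate scatter above
0.5 cycles is flagged but replicates are never dropped automatically.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REPLICATE_SD_FLAG = 0.5  # cycles


def _validate(ct: pd.DataFrame) -> pd.DataFrame:
    required = {"dog_id", "group", "gene", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return ct


def replicate_flags(ct: pd.DataFrame) -> pd.DataFrame:
    """Per (dog, gene) replicate mean/SD with a flag for SD > 0.5 cycles."""
    g = _validate(ct).groupby(["dog_id", "gene"])["ct"]
    out = g.agg(mean_ct="mean", sd_ct="std", n="size").reset_index()
    out["flag_high_sd"] = out["sd_ct"] > REPLICATE_SD_FLAG
    return out


def _dct(ct: pd.DataFrame, target: str, housekeeping: str) -> pd.DataFrame:
    means = ct.groupby(["dog_id", "group", "gene"])["ct"].mean().reset_index()
    piv = means.pivot(index=["dog_id", "group"], columns="gene", values="ct")
    for gene in (target, housekeeping):
        if gene not in piv.columns or piv[gene].isna().any():
            missing = (
                piv.index[piv[gene].isna()][0][0]
                if gene in piv.columns
                else "all dogs"
            )
            raise ValueError(f"missing Ct for gene {gene!r} (dog {missing})")
    out = (piv[target] - piv[housekeeping]).rename("dct").reset_index()
    return out


def delta_delta_ct(
    ct: pd.DataFrame, target: str, housekeeping: str
) -> dict:
    """ddCT comparison of one target against one housekeeping gene.

    Returns a dict with ddct, log2fc (= -ddct), fold, and the 95% CI of
    the log2FC from a Welch t interval on the case-vs-control dCT
    difference.
    """
    ct = _validate(ct)
    dct = _dct(ct, target, housekeeping)
    case = dct.loc[dct.group == "case", "dct"].to_numpy(dtype=float)
    ctrl = dct.loc[dct.group == "control", "dct"].to_numpy(dtype=float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 dogs per group")
    ddct = case.mean() - ctrl.mean()
    v1, v0 = case.var(ddof=1), ctrl.var(ddof=1)
    se2 = v1 / len(case) + v0 / len(ctrl)
    if se2 > 0:
        df = se2**2 / (
            (v1 / len(case)) ** 2 / (len(case) - 1)
            + (v0 / len(ctrl)) ** 2 / (len(ctrl) - 1)
        )
        half = stats.t.ppf(0.975, df) * np.sqrt(se2)
    else:
        half = 0.0
    return {
        "target": target,
        "housekeeping": housekeeping,
        "ddct": ddct,
        "log2fc": -ddct,
        "fold": 2.0 ** (-ddct),
        "ci_low": -ddct - half,
        "ci_high": -ddct + half,
        "n_case": len(case),
        "n_control": len(ctrl),
    }


def multi_housekeeping_summary(
    ct: pd.DataFrame, target: str, housekeeping_genes
) -> dict:
    """Summary of one target against several housekeeping genes.

    The point estimate is the mean of the per-housekeeping log2FCs; the
    pooled 95% CI comes from a Welch interval on the case-vs-control
    difference of the stacked per-(dog, housekeeping) dCT values, so the
    interval reflects both dog-to-dog and reference-gene spread.
    """
    housekeeping_genes = list(housekeeping_genes)
    if not housekeeping_genes:
        raise ValueError("need >= 1 housekeeping gene")
    singles = [delta_delta_ct(ct, target, hk) for hk in housekeeping_genes]
    if len(singles) == 1:
        return {**singles[0], "per_housekeeping": singles}
    stacked = pd.concat(
        [_dct(ct, target, hk) for hk in housekeeping_genes], ignore_index=True
    )
    case = stacked.loc[stacked.group == "case", "dct"].to_numpy(dtype=float)
    ctrl = stacked.loc[stacked.group == "control", "dct"].to_numpy(dtype=float)
    mean_l2fc = float(np.mean([s["log2fc"] for s in singles]))
    v1, v0 = case.var(ddof=1), ctrl.var(ddof=1)
    se2 = v1 / len(case) + v0 / len(ctrl)
    df = se2**2 / (
        (v1 / len(case)) ** 2 / (len(case) - 1)
        + (v0 / len(ctrl)) ** 2 / (len(ctrl) - 1)
    )
    half = stats.t.ppf(0.975, df) * np.sqrt(se2)
    ddct = case.mean() - ctrl.mean()
    return {
        "target": target,
        "housekeeping": "+".join(housekeeping_genes),
        "log2fc": mean_l2fc,
        "fold": 2.0**mean_l2fc,
        "ci_low": -ddct - half,
        "ci_high": -ddct + half,
        "per_housekeeping": singles,
    }
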