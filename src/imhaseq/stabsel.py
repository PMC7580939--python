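"""Stability selection of taxa predicting disease status.

Taxa counts are normalized to counts per million and log2(x+1)
transformed, then used as predictors in L1-penalized logistic regression
with case/control status as the response.  Stability selection runs the
LASSO on B complementary-pairs half-subsamples; a taxon is "stable" when
it is selected in at least a fraction pi of runs.  The per-run sparsity q
(variables allowed into each model) is calibrated from the per-family
error rate bound PFER >= q^2 / ((2*pi - 1) * p), so the expected number
of false selections is controlled at the chosen PFER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .io import CountMatrix

log = logging.getLogger(__name__)


def normalize_taxa(cm: CountMatrix) -> pd.DataFrame:
    """Counts-per-million then log2(x+1), per sample."""
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = cm.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"sample {bad!r} has zero library size")
    cpm = counts / lib * 1e6
    return pd.DataFrame(
        np.log2(cpm + 1.0), index=cm.counts.index, columns=cm.counts.columns
    )


def l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients minimizing logistic NLL + lam * ||beta||_1.

    The intercept is unpenalized.  lam -> inf drives all slopes to zero.
    """
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", fit_intercept=True,
        intercept_scaling=1e5,  # keeps the intercept effectively unpenalized
        tol=1e-8, max_iter=10_000, random_state=0,
    )
    with warnings.catch_warnings():
        # near-separable subsamples at tiny lambda legitimately hit the
        # iteration cap; the sign pattern is all stability selection needs
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_.ravel()


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambda: int = 50) -> np.ndarray:
    """Decreasing penalty grid from the smallest lambda that zeroes every
    slope down to 1% of it."""
    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max()
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max * 1.05, lam_max * 0.01, n_lambda)


@dataclass
class StabilityResult:
    frequencies: pd.Series  # taxon -> selection frequency in [0, 1]
    stable: pd.Series  # taxon -> bool at the frequency cutoff
    q: int  # per-run sparsity implied by the PFER bound
    B: int
    pi: float
    pfer: float


def stability_selection(
    X: pd.DataFrame,
    y: pd.Series,
    B: int = 100,
    pi: float = 0.6,
    pfer: float = 2.0,
    seed: int = 0,
    n_lambda: int = 50,
) -> StabilityResult:
    """Complementary-pairs stability selection over the LASSO path.

    Parameters
    ----------
    X
        samples x predictors design (e.g. normalized taxa, transposed).
    y
        binary labels aligned to X's rows ('case' -> 1).
    B
        total subsample fits (B/2 complementary pairs of size floor(n/2)).
    pi
        selection-frequency cutoff for calling a predictor stable.
    pfer
        per-family error rate bound; sets q = floor(sqrt(pfer*(2pi-1)*p)).

    Each run standardizes its subsample, walks the penalty path from the
    fully sparse end, and accumulates selected predictors until q is
    reached; frequencies are the fraction of runs selecting each one.
    """
    if len(X) < 10:
        raise ValueError("stability selection needs n >= 10")
    if not 0.5 < pi <= 1.0:
        raise ValueError("pi must lie in (0.5, 1]")
    yv = (
        (y == "case").astype(int) if y.dtype == object else y.astype(int)
    ).to_numpy()
    p = X.shape[1]
    q = int(np.floor(np.sqrt(pfer * (2 * pi - 1) * p)))
    if q < 1:
        raise ValueError(
            "PFER bound allows no selections (q < 1); increase pfer"
        )
    rng = np.random.default_rng(seed)
    n = len(X)
    half = n // 2
    Xv = X.to_numpy(dtype=float)
    hits = np.zeros(p)
    runs = 0
    for _ in range(B // 2 + B % 2):
        perm = rng.permutation(n)
        for idx in (perm[:half], perm[half : 2 * half]):
            if runs >= B:
                break
            sel = _path_select(Xv[idx], yv[idx], q, n_lambda)
            hits[sel] += 1
            runs += 1
    freqs = pd.Series(hits / runs, index=X.columns, name="selection_frequency")
    stable = (freqs >= pi).rename("stable")
    log.info(
        "stability selection: B=%d, q=%d, pi=%.2f, PFER=%.1f -> %d stable taxa",
        runs, q, pi, pfer, int(stable.sum()),
    )
    return StabilityResult(
        frequencies=freqs, stable=stable, q=q, B=runs, pi=pi, pfer=pfer
    )


def _path_select(X: np.ndarray, y: np.ndarray, q: int, n_lambda: int) -> np.ndarray:
    """Indices of the first q predictors entering the LASSO path."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    if len(np.unique(y)) < 2:  # degenerate subsample: nothing selectable
        return np.array([], dtype=int)
    selected: list[int] = []
    seen = set()
    for lam in _lambda_path(Xs, y, n_lambda):
        beta = l1_logistic(Xs, y, lam)
        active = np.flatnonzero(beta != 0)
        for j in active:
            if j not in seen:
                seen.add(j)
                selected.append(j)
        if len(selected) >= q:
            break
    return np.array(selected[:q], dtype=int)


def sensitivity_sweep(
    X: pd.DataFrame,
    y: pd.Series,
    pis=(0.6, 0.75),
    pfers=(1.0, 1.5, 2.0),
    B: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Stable sets across a grid of (pi, PFER) settings, to check that the
    selection is not an artifact of the exact cutoffs."""
    rows = []
    for pi in pis:
        for pfer in pfers:
            res = stability_selection(X, y, B=B, pi=pi, pfer=pfer, seed=seed)
            rows.append(
                {
                    "pi": pi,
                    "pfer": pfer,
                    "q": res.q,
                    "n_stable": int(res.stable.sum()),
                    "stable_taxa": ",".join(res.stable.index[res.stable]),
                }
            )
    return pd.DataFrame(rows)
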