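"""Summaries across many landscapes: PCA, spatial autocorrelation, outliers.

The landscape PCA treats genomic windows as observations and taxa (or
taxon pairs) as variables, on the correlation matrix: each column is
standardized before the decomposition, so PC1 captures the shared
topography of the landscapes rather than their absolute scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mimland.window_stats import z_transform

__all__ = ["PCAResult", "AutocorrResult", "landscape_pca", "autocorrelation_test", "outlier_deviation"]


@dataclass
class PCAResult:
    """Correlation-matrix PCA of a windows x variables landscape matrix.

    ``loadings`` are correlation-scaled (eigenvector * sqrt(eigenvalue)),
    so each entry is the correlation between a variable and the component
    and lies in [-1, 1].  ``components`` holds the raw orthonormal
    eigenvectors (n_components x n_variables).  PC1's sign is fixed so its
    mean loading is non-negative: high PC1 = high statistic.
    """

    pc1_scores: np.ndarray
    loadings: np.ndarray
    components: np.ndarray
    variance_explained: np.ndarray
    variables: list[str]
    scores: np.ndarray
    row_mean: np.ndarray
    complete_windows: np.ndarray
    n_dropped: int

    @property
    def pc1_z(self) -> np.ndarray:
        return z_transform(self.pc1_scores, name="PC1")


def landscape_pca(matrix, variables: list[str] | None = None) -> PCAResult:
    """PCA of a windows x variables matrix with listwise deletion.

    ``matrix`` may be a DataFrame (variable names from columns) or 2-D
    array.  Windows (rows) with any missing variable are dropped and
    counted; fewer than 3 complete windows is an error.  Also returns the
    per-window mean of the standardized variables (``row_mean``) for the
    PC1-vs-mean consistency check.
    """
    if isinstance(matrix, pd.DataFrame):
        variables = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        if variables is None:
            variables = [f"v{i}" for i in range(x.shape[1])]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    complete = np.isfinite(x).all(axis=1)
    n_dropped = int((~complete).sum())
    xc = x[complete]
    if xc.shape[0] < 3:
        raise ValueError("fewer than 3 complete windows")
    sd = xc.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"zero-variance variables: {bad}")
    z = (xc - xc.mean(axis=0)) / sd

    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / n  # eigenvalues of the correlation matrix
    var_frac = eigvals / eigvals.sum()
    scores = u * s
    loadings = vt.T * np.sqrt(eigvals)

    if loadings[:, 0].mean() < 0:
        loadings[:, 0] *= -1
        vt[0] *= -1
        scores[:, 0] *= -1

    pc1 = np.full(x.shape[0], np.nan)
    pc1[complete] = scores[:, 0]
    row_mean = np.full(x.shape[0], np.nan)
    row_mean[complete] = z.mean(axis=1)
    return PCAResult(
        pc1_scores=pc1,
        loadings=loadings,
        components=vt,
        variance_explained=var_frac,
        variables=variables,
        scores=scores,
        row_mean=row_mean,
        complete_windows=complete,
        n_dropped=n_dropped,
    )


@dataclass
class AutocorrResult:
    lag_bp: int
    lag_windows: int
    n_perm: int
    observed: dict[str, float]  # per linkage group
    p_value: dict[str, float]


def _lag_corr(values: np.ndarray, k: int) -> float:
    x, y = values[:-k], values[k:]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def autocorrelation_test(
    series,
    chroms,
    lag_bp: int,
    grid_step_bp: int,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AutocorrResult:
    """Permutation test for spatial clustering of a window landscape.

    The observed statistic is the per-linkage-group Pearson correlation of
    window values ``k`` grid steps apart, ``k = round(lag_bp /
    grid_step_bp)``.  The null permutes the genome-wide values jointly,
    reassigns them to positions, and recomputes per LG; the one-sided
    p-value is ``(#null >= observed + 1) / (n_perm + 1)`` (clustering =
    positive autocorrelation).  LGs with fewer than k + 2 windows are
    reported missing.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(series, dtype=float)
    chroms = np.asarray(chroms)
    ok = np.isfinite(x)
    if ok.sum() < 2 or x[ok].std() == 0:
        raise ValueError("series has zero variance")
    k = max(1, round(lag_bp / grid_step_bp))
    rng = np.random.default_rng(seed)
    lgs = list(dict.fromkeys(chroms))
    lg_slices = {lg: np.flatnonzero(chroms == lg) for lg in lgs}

    observed = {}
    for lg, idx in lg_slices.items():
        observed[lg] = _lag_corr(x[idx], k) if len(idx) >= k + 2 else np.nan

    null = {lg: np.empty(n_perm) for lg in lgs}
    for p in range(n_perm):
        perm = rng.permutation(x)
        for lg, idx in lg_slices.items():
            null[lg][p] = _lag_corr(perm[idx], k) if len(idx) >= k + 2 else np.nan
    pvals = {}
    for lg in lgs:
        if not np.isfinite(observed[lg]):
            pvals[lg] = np.nan
            continue
        pvals[lg] = (np.sum(null[lg] >= observed[lg]) + 1) / (n_perm + 1)
    return AutocorrResult(
        lag_bp=lag_bp,
        lag_windows=k,
        n_perm=n_perm,
        observed=observed,
        p_value=pvals,
    )


def outlier_deviation(z_fst_pair, pc1_z, coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-window deviation (SD units) of one pair's Z-F_ST above PC1 Z-F_ST.

    Positive values mark windows where the pair is more differentiated
    than the shared landscape predicts; the returned table is annotated
    with the rank of each window (1 = largest deviation).
    """
    a = np.asarray(z_fst_pair, dtype=float)
    b = np.asarray(pc1_z, dtype=float)
    if a.shape != b.shape:
        raise ValueError("window grids do not match")
    dev = a - b
    order = np.argsort(np.where(np.isfinite(dev), -dev, np.inf), kind="stable")
    rank = np.empty(len(dev), dtype=float)
    rank[order] = np.arange(1, len(dev) + 1)
    rank[~np.isfinite(dev)] = np.nan
    out = pd.DataFrame({"deviation": dev, "rank": rank})
    if coords is not None:
        out = pd.concat([coords.reset_index(drop=True), out], axis=1)
    return out
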