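"""Correlation PCA of locality-by-bioclim matrices and a permutation test of
pathway-group separation along a principal axis.

The 19 WorldClim bioclimatic variables mix units (degrees C and mm), so the
PCA standardizes every column to zero mean and unit variance before the
singular value decomposition (correlation PCA).  Loadings carry a
deterministic sign convention -- the largest-magnitude entry of each column
is positive -- so results are reproducible across runs and platforms.
Axis attribution ranks variables by absolute loading; group separation is a
one-way between/within variance ratio (F-type) of the scores on one axis,
calibrated by label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import ValidationError

BIOCLIM_VARS = tuple(f"bio{i}" for i in range(1, 20))


@dataclass
class PCAResult:
    """Loadings (variables x axes), scores (rows x axes) and variance
    fractions of a correlation PCA."""

    loadings: pd.DataFrame  # index = variable names, columns PC1..PCk
    scores: pd.DataFrame  # index = row index of the input matrix
    explained_variance_ratio: np.ndarray  # length k, non-increasing
    column_means: np.ndarray
    column_sds: np.ndarray


def pca_fit(matrix: pd.DataFrame, k: int = 2) -> PCAResult:
    """Fit a correlation PCA with k axes via SVD of the standardized matrix.

    Requires n > k >= 2.  A zero-variance column is an error naming the
    column (it cannot be standardized).
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if not (2 <= k <= p):
        raise ValidationError(f"need 2 <= k <= {p}, got k={k}")
    if n <= k:
        raise ValidationError(f"need more rows ({n}) than axes ({k})")
    if np.isnan(X).any():
        raise ValidationError("matrix contains missing cells")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sds == 0)
    if zero_var.size:
        names = [str(matrix.columns[j]) for j in zero_var]
        raise ValidationError(f"zero-variance column(s): {names}")
    Z = (X - means) / sds
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var_ratio = (s**2) / np.sum(s**2)
    loadings = Vt.T[:, :k].copy()
    scores = (U[:, :k] * s[:k]).copy()
    # deterministic sign: largest-|loading| entry of each axis is positive
    for j in range(k):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    axis_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=axis_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=axis_names),
        explained_variance_ratio=var_ratio[:k],
        column_means=means,
        column_sds=sds,
    )


def axis_attribution(result: PCAResult, top_m: int = 4) -> dict[str, list[str]]:
    """Top-m variables per axis, ranked by |loading| (ties broken by the
    variable's column index, i.e. input order)."""
    out: dict[str, list[str]] = {}
    variables = list(result.loadings.index)
    for axis in result.loadings.columns:
        mags = result.loadings[axis].abs().to_numpy()
        order = sorted(range(len(variables)), key=lambda i: (-mags[i], i))
        out[axis] = [variables[i] for i in order[:top_m]]
    return out


@dataclass(frozen=True)
class SeparationResult:
    """Between/within variance ratio on one axis with a permutation p."""

    f_ratio: float
    p_value: float
    n_permutations: int


def _f_ratio(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = values.size
    counts = np.bincount(codes, minlength=k)
    sums = np.bincount(codes, weights=values, minlength=k)
    means = sums / counts
    grand = values.mean()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[codes]) ** 2))
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        return np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def group_separation(
    scores: pd.DataFrame,
    labels,
    axis: str = "PC1",
    n_permutations: int = 999,
    seed: int | None = 0,
) -> SeparationResult:
    """Permutation F-test of group separation of the scores on one axis.

    p = (1 + #{permuted F >= observed F}) / (n_permutations + 1).  Requires
    at least two groups with at least two points each.
    """
    values = scores[axis].to_numpy(dtype=float)
    labels = np.asarray(labels)
    if labels.size != values.size:
        raise ValidationError("labels and scores disagree in length")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValidationError("need at least two groups")
    if np.bincount(codes).min() < 2:
        raise ValidationError("every group needs at least two points")
    if n_permutations < 1:
        raise ValidationError("need at least one permutation")
    k = uniq.size
    observed = _f_ratio(values, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _f_ratio(values, perm, k) >= observed:
            hits += 1
    return SeparationResult(
        f_ratio=observed,
        p_value=(1 + hits) / (n_permutations + 1),
        n_permutations=n_permutations,
    )


def load_climate_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Extract and validate the 19 bioclim columns from a locality table."""
    missing = [v for v in BIOCLIM_VARS if v not in table.columns]
    if missing:
        raise ValidationError(f"climate table missing columns {missing}")
    matrix = table.loc[:, list(BIOCLIM_VARS)].astype(float)
    if matrix.isna().any().any():
        raise ValidationError("climate matrix contains missing cells")
    return matrix
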