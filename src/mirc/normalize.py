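"""Normalization and expression summaries for small-RNA count data.

Library size is the per-sample sum of *biological* (non-calibrator) reads:
spike-in calibrators are added at a fixed amount during library preparation
and must not absorb biological signal.  Calibrator counts instead yield
per-sample multiplicative size factors (geometric mean, unit-geomean scaled)
that can be composed with CPM as effective library sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CountMatrix, ExprMatrix, ValidationError


def library_sizes(counts: CountMatrix) -> pd.Series:
    """Per-sample library size over non-calibrator features."""
    bio = ~counts.calibrator_mask()
    return counts.counts.loc[bio].sum(axis=0)


def cpm(
    counts: CountMatrix,
    log: bool = False,
    prior_count: float = 0.5,
    size_factors: pd.Series | None = None,
) -> ExprMatrix:
    """Counts-per-million over biological features.

    Unlogged: ``count / effective_libsize * 1e6`` with
    ``effective_libsize = libsize * size_factor``.  Logged:
    ``log2((count + prior_count) / (effective_libsize + 2*prior_count) * 1e6)``.
    Calibrator features are excluded from both the library size and the
    output matrix.
    """
    if prior_count < 0:
        raise ValidationError("prior_count must be >= 0")
    lib = library_sizes(counts).astype(float)
    if (lib <= 0).any():
        empty = lib.index[lib <= 0].tolist()
        raise ValidationError(f"zero library size in sample(s) {empty[:5]}")
    if size_factors is not None:
        sf = pd.Series(size_factors).reindex(lib.index)
        if sf.isna().any() or (sf <= 0).any():
            raise ValidationError("size_factors must be positive for all samples")
        lib = lib * sf
    bio = counts.counts.loc[~counts.calibrator_mask()].astype(float)
    if log:
        vals = np.log2((bio + prior_count).div(lib + 2 * prior_count, axis=1) * 1e6)
        return ExprMatrix(vals, scale="log2_cpm")
    return ExprMatrix(bio.div(lib, axis=1) * 1e6, scale="cpm")


def calibrator_size_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample size factors from spike-in calibrators.

    factor_s = geometric mean of calibrator counts in sample s, rescaled so
    that the geometric mean of the factors over samples is 1.  A sample in
    which every calibrator count is zero is an error (the geometric mean is
    undefined; no pseudocount is applied).
    """
    cal = counts.counts.loc[counts.calibrator_mask()]
    if cal.shape[0] == 0:
        raise ValidationError("no calibrator features present")
    dead = cal.columns[(cal == 0).all(axis=0)].tolist()
    if dead:
        raise ValidationError(f"all calibrator counts zero in sample(s) {dead}")
    if (cal.to_numpy() == 0).any():
        # geometric mean over the nonzero calibrators only, per sample
        logs = np.log(cal.where(cal > 0))
        gm = np.exp(logs.mean(axis=0, skipna=True))
    else:
        gm = np.exp(np.log(cal).mean(axis=0))
    factors = gm / np.exp(np.log(gm).mean())
    factors.name = "size_factor"
    return factors


def filter_expressed(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
    within: list[str] | None = None,
) -> CountMatrix:
    """Keep features with CPM >= min_cpm in >= min_fraction of the ``within``
    samples (both thresholds inclusive); calibrators are always dropped.

    The CPM used for screening is unlogged and computed within the selected
    samples, matching per-comparison filtering.
    """
    if not 0 <= min_fraction <= 1:
        raise ValidationError("min_fraction must be in [0, 1]")
    sub = counts if within is None else counts.subset_samples(within)
    vals = cpm(sub, log=False).values
    frac = (vals >= min_cpm).mean(axis=1)
    keep = frac[frac >= min_fraction].index
    bio = counts.drop_calibrators()
    kept = bio.counts.loc[bio.counts.index.isin(keep)]
    return CountMatrix(
        kept.copy(),
        {f: bio.feature_class[f] for f in kept.index},
        {f: False for f in kept.index},
    )


def class_composition(counts: CountMatrix) -> pd.DataFrame:
    """Per-sample fraction of biological reads per RNA class.

    Returns samples x classes; rows sum to 1.
    """
    bio = counts.drop_calibrators()
    totals = bio.counts.sum(axis=0)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0].tolist()
        raise ValidationError(f"no biological reads in sample(s) {empty[:5]}")
    cls = pd.Series(bio.class_array(), index=bio.counts.index)
    by_class = bio.counts.groupby(cls).sum()
    return (by_class / totals).T


def quantile_normalize(expr: ExprMatrix) -> ExprMatrix:
    """Force every sample (column) onto the common reference distribution:
    the row-wise mean of per-column order statistics.  Ties within a column
    receive the mean of their tied reference values.
    """
    vals = expr.values
    if vals.shape[1] == 1:
        warnings.warn("quantile_normalize with a single sample is the identity")
        return ExprMatrix(vals.copy(), scale=expr.scale)
    arr = vals.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(ref)
        ranked[order] = ref
        # average reference values over tied observations
        out[:, j] = pd.Series(ranked).groupby(col).transform("mean").to_numpy()
    return ExprMatrix(
        pd.DataFrame(out, index=vals.index, columns=vals.columns), scale=expr.scale
    )


def pca(expr: ExprMatrix, n_components: int = 2):
    """Feature-centered PCA of samples via SVD.

    Returns (scores, loadings, variance_explained): ``scores`` is a
    samples x components DataFrame, ``loadings`` features x components, and
    ``variance_explained`` the per-component fraction of total variance
    (sums to <= 1).  Retaining all components reconstructs the centered
    matrix as loadings @ scores.T.
    """
    vals = expr.values
    n_feat, n_samp = vals.shape
    if n_samp < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if n_components > min(n_feat, n_samp):
        raise ValidationError(
            f"n_components={n_components} exceeds min(dim)={min(n_feat, n_samp)}"
        )
    centered = vals.to_numpy(dtype=float) - vals.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = (s**2).sum()
    var_explained = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (vt[:n_components].T * s[:n_components]), index=vals.columns, columns=comp
    )
    loadings = pd.DataFrame(u[:, :n_components], index=vals.index, columns=comp)
    return scores, loadings, var_explained
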