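"""Precision-weighted linear-model differential expression with an
empirical-Bayes moderated t-statistic.

The engine follows the standard small-sample RNA-seq workflow: counts are
log2-CPM transformed, a per-feature linear model yields a mean-variance
trend (LOWESS of sqrt residual sd against mean log2 count), per-observation
precision weights are the predicted sd to the power -4, and per-feature
residual variances are shrunk toward a global prior fitted by moment
matching on log s^2 (closed form via trigamma inversion).  The moderated t
has d + d0 degrees of freedom.  Benjamini-Hochberg step-up adjusts p-values
per contrast.

Sample age (a degradation proxy) and other clinical covariates enter the
design matrix as ordinary columns; matched tumor/normal designs add patient
indicator columns (fixed-effect pairing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix, ExprMatrix, ValidationError
from .normalize import cpm, filter_expressed, library_sizes


@dataclass
class ModelFit:
    """Per-feature WLS fits plus the global variance prior."""

    coefficients: pd.DataFrame  # features x design columns
    stdev_unscaled: pd.DataFrame  # features x design columns
    sigma2: pd.Series  # residual variances s^2
    df_residual: float
    df_prior: float  # d0, may be inf
    var_prior: float  # s0^2
    sigma2_post: pd.Series  # shrunken s~^2

    def __post_init__(self) -> None:
        lo = np.minimum(self.sigma2.to_numpy(), self.var_prior)
        hi = np.maximum(self.sigma2.to_numpy(), self.var_prior)
        post = self.sigma2_post.to_numpy()
        if ((post < lo - 1e-9) | (post > hi + 1e-9)).any():
            raise AssertionError("posterior variance outside [min, max] bracket")


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    meta: pd.DataFrame,
    group: pd.Series,
    adjust_for: list[str] | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Intercept + binary group indicator (+ covariates, + patient blocks).

    ``group`` is a boolean Series indexed by sample_id (True = positive
    group).  With ``paired=True`` one indicator column per patient beyond the
    first is added; incomplete pairs are rejected upstream.
    """
    cols = {"intercept": np.ones(len(meta)), "group": group.loc[meta.index].astype(float)}
    for cov in adjust_for or []:
        v = pd.to_numeric(meta[cov], errors="coerce")
        if v.isna().any():
            raise ValidationError(f"covariate {cov!r} has missing values")
        cols[cov] = v.to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=meta.index)
    if paired:
        patients = meta["patient_id"].astype(str)
        dummies = pd.get_dummies(patients, prefix="patient", drop_first=True).astype(float)
        design = pd.concat([design, dummies], axis=1)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValidationError(
            f"design matrix is rank-deficient (rank {rank} < {design.shape[1]} columns); "
            "a covariate is confounded with the group or pairing structure"
        )
    return design


# ---------------------------------------------------------------------------
# voom weights


def voom_weights(
    counts: CountMatrix,
    design: pd.DataFrame,
    span: float = 0.5,
    size_factors: pd.Series | None = None,
) -> ExprMatrix:
    """Log2-CPM values with per-observation mean-variance precision weights.

    Fits an unweighted linear model per feature, smooths sqrt(residual sd)
    against mean log2 count with LOWESS, predicts each observation's sd from
    its fitted log2 count, and sets weight = predicted_sd**-4.  Predictions
    outside the fitted trend are clipped to the trend's range.
    """
    X = design.loc[counts.sample_ids].to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError("design matrix is rank-deficient")
    if n - rank < 1:
        raise ValidationError("no residual degrees of freedom")

    lib = library_sizes(counts).astype(float)
    if size_factors is not None:
        lib = lib * pd.Series(size_factors).reindex(lib.index)
    expr = cpm(counts, log=True, prior_count=0.5, size_factors=size_factors)
    Y = expr.values.to_numpy(dtype=float)

    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T  # features x p
    fitted = beta @ X.T
    resid = Y - fitted
    df = n - rank
    sigma = np.sqrt((resid**2).sum(axis=1) / df)

    # mean log2 count abundance: mean log2-cpm shifted back to count scale
    sx = Y.mean(axis=1) + np.mean(np.log2(lib.to_numpy() + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = np.isfinite(sx) & np.isfinite(sy)
    trend = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    # per-observation fitted log2 count, then interpolate the trend
    fitted_logcount = fitted + np.log2(lib.to_numpy() + 1.0) - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)  # np.interp clips at ends
    pred_sqrt_sd = np.clip(pred_sqrt_sd, max(ty.min(), 1e-6), None)
    W = pred_sqrt_sd**-4.0

    return ExprMatrix(
        expr.values,
        scale="log2_cpm",
        weights=pd.DataFrame(W, index=expr.values.index, columns=expr.values.columns),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to the observed s^2 distribution.

    Works on z = log(s^2): its theoretical variance given a common true
    variance is trigamma(df/2); excess variance identifies a finite prior
    df d0 via trigamma inversion, and the prior variance s0^2 follows from
    the mean.  Returns (d0, s0^2); d0 = inf when no excess variance.
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def squeeze_var(sigma2: np.ndarray, df: float, d0: float, s02: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(sigma2, dtype=float), s02)
    return (d0 * s02 + df * sigma2) / (d0 + df)


def fit_and_moderate(
    expr: ExprMatrix,
    design: pd.DataFrame,
    coef: str = "group",
    prior_df: float | None = None,
) -> tuple[ModelFit, pd.DataFrame]:
    """Weighted least squares per feature + moderated t for one coefficient.

    ``prior_df`` overrides the estimated d0 (0 recovers the classical t,
    inf pools all features to the common prior variance).  Returns the fit
    and a DE table (feature_id, logFC, aveExpr, t, p) without adjustment.
    """
    if coef not in design.columns:
        raise ValidationError(f"design has no column {coef!r}")
    X = design.loc[expr.sample_ids].to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError("design matrix is rank-deficient")
    df_resid = n - rank
    Y = expr.values.to_numpy(dtype=float)
    W = expr.weights.to_numpy(dtype=float) if expr.weights is not None else np.ones_like(Y)
    G = Y.shape[0]
    ci = list(design.columns).index(coef)

    beta = np.empty((G, p))
    unscaled = np.empty((G, p))
    s2 = np.empty(G)
    for g in range(G):
        w = W[g]
        Xw = X * np.sqrt(w)[:, None]
        yw = Y[g] * np.sqrt(w)
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        b = xtx_inv @ (Xw.T @ yw)
        r = yw - Xw @ b
        beta[g] = b
        unscaled[g] = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0))
        s2[g] = (r @ r) / df_resid if df_resid > 0 else np.nan

    if df_resid == 0:
        if prior_df is None or not np.isfinite(prior_df):
            raise ValidationError("no residual df and no finite prior df")

    if prior_df is not None:
        d0 = float(prior_df)
        if np.isinf(d0):
            s02 = float(np.nanmean(s2))  # pooled variance across features
        elif d0 == 0:
            s02 = 1.0  # irrelevant: posterior equals s2
        else:
            _, s02 = estimate_prior(s2, max(df_resid, 1))
    else:
        d0, s02 = estimate_prior(s2, df_resid)

    s2_post = squeeze_var(s2, df_resid, d0, s02) if d0 > 0 else s2.copy()
    se = unscaled[:, ci] * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[:, ci] / se
    df_total = df_resid + (0.0 if not np.isfinite(d0) else d0)
    if np.isfinite(d0):
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))

    idx = expr.values.index
    fit = ModelFit(
        coefficients=pd.DataFrame(beta, index=idx, columns=design.columns),
        stdev_unscaled=pd.DataFrame(unscaled, index=idx, columns=design.columns),
        sigma2=pd.Series(s2, index=idx),
        df_residual=float(df_resid),
        df_prior=float(d0),
        var_prior=float(s02),
        sigma2_post=pd.Series(s2_post, index=idx),
    )
    de = pd.DataFrame(
        {
            "feature_id": idx,
            "logFC": beta[:, ci],
            "aveExpr": Y.mean(axis=1),
            "t": tstat,
            "p": pvals,
        }
    ).reset_index(drop=True)
    return fit, de


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# full contrast runner


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison: which samples, what defines the groups,
    which covariates to adjust for, and whether the design is paired."""

    name: str
    compartments: tuple[str, ...]
    group_by: str  # "compartment" or a clinical column (hbv/cirrhosis/surgery)
    positive: str | bool  # positive-group level
    adjust_for: tuple[str, ...] = ()
    paired: bool = False


STANDARD_CONTRASTS = {
    "tumor_vs_normal": ContrastSpec(
        "tumor_vs_normal", ("tumor", "normal"), "compartment", "tumor", paired=True
    ),
    "exo_vs_serum": ContrastSpec(
        "exo_vs_serum", ("exosome", "serum"), "compartment", "exosome", paired=True
    ),
    "cancer_vs_control_serum": ContrastSpec(
        "cancer_vs_control_serum", ("serum", "control_serum"), "compartment", "serum"
    ),
}


def clinical_contrast(name: str, compartment: str, adjust_for=("sample_age",)) -> ContrastSpec:
    """A clinical-covariate contrast within one compartment, sample-age
    adjusted by default (HBV, cirrhosis, transplantation-vs-resection)."""
    col, positive = {
        "HBV": ("hbv", True),
        "cirrhosis": ("cirrhosis", True),
        "surgery": ("surgery", "transplantation"),
    }[name]
    return ContrastSpec(
        f"{name}_in_{compartment}", (compartment,), col, positive, tuple(adjust_for)
    )


def run_contrast(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    contrast: ContrastSpec | str,
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
    size_factors: pd.Series | None = None,
    span: float = 0.5,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Filter -> voom -> moderated t -> BH for one contrast.

    Returns the DE table with columns (feature_id, logFC, aveExpr, t, p,
    adj_p, significant); ``.attrs`` records the contrast name, group sizes
    and thresholds.
    """
    if isinstance(contrast, str):
        contrast = STANDARD_CONTRASTS[contrast]
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")

    meta = metadata[metadata["compartment"].isin(contrast.compartments)]
    col = meta[contrast.group_by]
    if contrast.group_by != "compartment":
        meta = meta[col.notna()]
        col = meta[contrast.group_by]
    group = col == contrast.positive
    if group.sum() == 0 or (~group).sum() == 0:
        raise ValidationError(
            f"contrast {contrast.name!r}: both groups must be nonempty"
        )
    if contrast.paired:
        # keep only patients observed in both groups
        per_patient = meta.groupby("patient_id")[contrast.group_by].nunique()
        complete = per_patient[per_patient == 2].index
        meta = meta[meta["patient_id"].isin(complete)]
        group = meta[contrast.group_by] == contrast.positive
        if meta.empty:
            raise ValidationError(f"contrast {contrast.name!r}: no complete pairs")

    sample_ids = meta["sample_id"].tolist()
    sub = counts.subset_samples(sample_ids)
    if size_factors is not None:
        size_factors = pd.Series(size_factors).reindex(sample_ids)

    filtered = filter_expressed(sub, min_cpm=min_cpm, min_fraction=min_fraction)
    design = build_design(
        meta.set_index("sample_id"),
        group.set_axis(meta["sample_id"]),
        adjust_for=list(contrast.adjust_for),
        paired=contrast.paired,
    )
    expr = voom_weights(filtered, design, span=span, size_factors=size_factors)
    _, de = fit_and_moderate(expr, design, coef="group", prior_df=prior_df)
    de["adj_p"] = bh_adjust(de["p"].to_numpy())
    de["significant"] = de["adj_p"] < alpha
    de.attrs.update(
        contrast=contrast.name,
        n_positive=int(group.sum()),
        n_negative=int((~group).sum()),
        alpha=alpha,
        min_cpm=min_cpm,
        min_fraction=min_fraction,
    )
    return de
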