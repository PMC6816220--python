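"""The moderated-t engine: BH, limiting cases, voom weights, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirc
from mirc.diffexpr import (
    ContrastSpec,
    bh_adjust,
    build_design,
    estimate_prior,
    fit_and_moderate,
    trigamma_inverse,
    voom_weights,
)
from mirc.io import CountMatrix, ExprMatrix, ValidationError
from mirc.simulate import PlantedEffect, SimConfig


# --- BH -------------------------------------------------------------------


def test_bh_step_up_hand_value():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


@pytest.mark.parametrize("p,expected", [([0.5], [0.5]), ([1, 1, 1], [1, 1, 1])])
def test_bh_trivial_cases(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=200)
    np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


def test_bh_order_equivariant():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


def test_bh_monotone_consistency():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=100)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert (adj >= p - 1e-15).all() and ((0 <= adj) & (adj <= 1)).all()


# --- trigamma / prior estimation -----------------------------------------


@pytest.mark.parametrize("x", [0.1, 0.7, 2.0, 15.0])
def test_trigamma_inverse_round_trip(x):
    from scipy.special import polygamma

    assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)


def test_prior_estimation_recovers_truth():
    """s^2 ~ s0^2 * (chi2_d / d) / (chi2_d0 / d0)-style scaled F: the moment
    estimator recovers (d0, s0^2) approximately at 20k features."""
    rng = np.random.default_rng(3)
    d, d0, s02 = 6.0, 8.0, 2.0
    true_var = s02 * d0 / rng.chisquare(d0, 20_000)
    s2 = true_var * rng.chisquare(d, 20_000) / d
    d0_hat, s02_hat = estimate_prior(s2, d)
    assert d0_hat == pytest.approx(d0, rel=0.2)
    assert s02_hat == pytest.approx(s02, rel=0.1)


# --- limiting-case exactness ----------------------------------------------


def toy_expr(seed=0, G=25, n=12):
    rng = np.random.default_rng(seed)
    design = pd.DataFrame(
        {"intercept": np.ones(n), "group": [0] * (n // 2) + [1] * (n // 2)},
        index=[f"s{i}" for i in range(n)],
    )
    vals = pd.DataFrame(
        rng.normal(size=(G, n)), index=[f"f{i}" for i in range(G)], columns=design.index
    )
    return ExprMatrix(vals), design


def test_prior_df_zero_equals_classical_t():
    expr, design = toy_expr()
    _, de = fit_and_moderate(expr, design, "group", prior_df=0.0)
    n2 = 6
    for f in expr.feature_ids:
        a = expr.values.loc[f].iloc[:n2]
        b = expr.values.loc[f].iloc[n2:]
        t_ref = stats.ttest_ind(b, a, equal_var=True)
        row = de.set_index("feature_id").loc[f]
        assert row["t"] == pytest.approx(t_ref.statistic, abs=1e-10)
        assert row["p"] == pytest.approx(t_ref.pvalue, abs=1e-10)


def test_prior_df_inf_equals_pooled_variance_t():
    expr, design = toy_expr(seed=1)
    fit, de = fit_and_moderate(expr, design, "group", prior_df=np.inf)
    X = design.to_numpy()
    n = X.shape[0]
    resid_var = []
    for f in expr.feature_ids:
        y = expr.values.loc[f].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        resid_var.append((r @ r) / (n - 2))
    pooled = np.mean(resid_var)
    assert np.allclose(fit.sigma2_post, pooled)
    se = np.sqrt(pooled * 4 / n)  # balanced two-group: var(beta) = s2*(1/n1+1/n2)
    for f, row in de.set_index("feature_id").iterrows():
        diff = (
            expr.values.loc[f].iloc[6:].mean() - expr.values.loc[f].iloc[:6].mean()
        )
        assert row["t"] == pytest.approx(diff / se, abs=1e-10)


def test_posterior_variance_between_extremes():
    expr, design = toy_expr(seed=2)
    fit, _ = fit_and_moderate(expr, design, "group")
    lo = np.minimum(fit.sigma2, fit.var_prior)
    hi = np.maximum(fit.sigma2, fit.var_prior)
    assert ((fit.sigma2_post >= lo - 1e-12) & (fit.sigma2_post <= hi + 1e-12)).all()


def test_moderated_t_monotone_in_coefficient():
    expr, design = toy_expr(seed=3)
    fit, de = fit_and_moderate(expr, design, "group")
    scale = de["logFC"].abs() / (
        fit.stdev_unscaled["group"].to_numpy() * np.sqrt(fit.sigma2_post.to_numpy())
    )
    np.testing.assert_allclose(de["t"].abs(), scale, atol=1e-12)


# --- voom weights ---------------------------------------------------------


def make_counts(arr, samples=None):
    G, n = arr.shape
    samples = samples or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(G)], columns=samples)
    return CountMatrix(df, {f: "miRNA" for f in df.index})


def two_group_design(n):
    return pd.DataFrame(
        {"intercept": np.ones(n), "group": [0] * (n // 2) + [1] * (n - n // 2)},
        index=[f"s{i}" for i in range(n)],
    )


def test_voom_flat_trend_near_constant_weights():
    """Homoscedastic log-scale data disguised as counts (constant log-sd
    across a wide abundance range, equal libraries) gives a flat trend and
    weights varying by < 20%."""
    rng = np.random.default_rng(6)
    abundances = np.linspace(6, 12, 600)
    logvals = abundances[:, None] + rng.normal(0, 0.1, size=(600, 20))
    arr = np.round(2.0**logvals).astype(int)
    expr = voom_weights(make_counts(arr), two_group_design(20))
    w = expr.weights.to_numpy()
    assert w.max() / w.min() < 1.2


def test_voom_low_counts_downweighted():
    """NB counts: weights increase with abundance in the low range."""
    rng = np.random.default_rng(5)
    means = np.geomspace(5, 5000, 120)
    arr = rng.negative_binomial(5, 5 / (5 + means[:, None]), size=(120, 12))
    expr = voom_weights(make_counts(arr), two_group_design(12))
    mean_w = expr.weights.mean(axis=1)
    rho = stats.spearmanr(means, mean_w).statistic
    assert rho > 0.5


def test_voom_identical_rows_identical_weights():
    rng = np.random.default_rng(6)
    row = rng.poisson(200, size=12)
    arr = np.vstack([row, row, rng.poisson(50, size=(40, 12))])
    expr = voom_weights(make_counts(arr), two_group_design(12))
    np.testing.assert_array_equal(
        expr.weights.iloc[0].to_numpy(), expr.weights.iloc[1].to_numpy()
    )


def test_voom_rank_deficient_design_errors():
    rng = np.random.default_rng(7)
    arr = rng.poisson(100, size=(20, 6))
    design = two_group_design(6)
    design["dup"] = design["group"]
    with pytest.raises(ValidationError, match="rank"):
        voom_weights(make_counts(arr), design)


# --- run_contrast ---------------------------------------------------------


def sim_counts(n_pat, planted=(), seed=0, **kw):
    cfg = SimConfig(
        n_patients_discovery=n_pat,
        n_patients_validation=0,
        n_controls=kw.pop("n_controls", 0),
        n_mirna=kw.pop("n_mirna", 80),
        n_other_ncrna={"snoRNA": 10, "tRNA": 10, "scRNA": 5, "other": 5},
        planted_effects=planted,
        age_effect_sd=0.0,
        seed=seed,
        **kw,
    )
    return mirc.simulate_cohort(cfg)


def test_label_swap_negates_logfc():
    counts, meta = sim_counts(10, seed=8)
    fwd = ContrastSpec("fwd", ("tumor", "normal"), "compartment", "tumor")
    rev = ContrastSpec("rev", ("tumor", "normal"), "compartment", "normal")
    de_f = mirc.run_contrast(counts, meta, fwd)
    de_r = mirc.run_contrast(counts, meta, rev)
    merged = de_f.merge(de_r, on="feature_id", suffixes=("_f", "_r"))
    np.testing.assert_allclose(merged["logFC_f"], -merged["logFC_r"], atol=1e-10)
    np.testing.assert_allclose(merged["p_f"], merged["p_r"], atol=1e-10)


def test_confounded_covariate_raises_rank_error():
    counts, meta = sim_counts(8, seed=9)
    meta = meta.copy()
    # covariate identical to the group indicator
    meta["shadow"] = (meta["compartment"] == "tumor").astype(float)
    spec = ContrastSpec(
        "confounded", ("tumor", "normal"), "compartment", "tumor", adjust_for=("shadow",)
    )
    with pytest.raises(ValidationError, match="rank"):
        mirc.run_contrast(counts, meta, spec)


def test_pairing_improves_power_with_patient_effects():
    """With strong patient-level intercepts, the paired design detects a
    planted effect that the unpaired design dilutes."""
    rng = np.random.default_rng(10)
    n_pat, G = 12, 60
    pat_effect = rng.normal(0, 2.0, size=n_pat)
    mu = 2.0 ** rng.normal(7, 1.5, size=G)
    rows, samples, meta_rows = [], [], []
    for p in range(n_pat):
        for comp in ("tumor", "normal"):
            boost = np.ones(G)
            boost[:6] = 4.0 if comp == "tumor" else 1.0  # planted log2fc = 2
            lam = mu * boost * 2.0 ** pat_effect[p]
            rows.append(rng.poisson(lam))
            samples.append(f"P{p}_{comp}")
            meta_rows.append(
                dict(
                    sample_id=f"P{p}_{comp}",
                    patient_id=f"P{p}",
                    compartment=comp,
                    cohort="discovery",
                    sample_age=0.0,
                )
            )
    counts = CountMatrix(
        pd.DataFrame(np.array(rows).T, index=[f"f{i}" for i in range(G)], columns=samples),
        {f"f{i}": "miRNA" for i in range(G)},
    )
    meta = pd.DataFrame(meta_rows)
    paired = ContrastSpec("p", ("tumor", "normal"), "compartment", "tumor", paired=True)
    unpaired = ContrastSpec("u", ("tumor", "normal"), "compartment", "tumor", paired=False)
    de_p = mirc.run_contrast(counts, meta, paired).set_index("feature_id")
    de_u = mirc.run_contrast(counts, meta, unpaired).set_index("feature_id")
    planted = [f"f{i}" for i in range(6)]
    hits_p = int(de_p.loc[de_p.index.isin(planted), "significant"].sum())
    hits_u = int(de_u.loc[de_u.index.isin(planted), "significant"].sum())
    assert hits_p >= hits_u
    assert hits_p >= 5


def test_null_moderated_t_matches_t_distribution():
    """Homoscedastic null: moderated t follows t with d+d0 df (KS)."""
    rng = np.random.default_rng(11)
    expr = ExprMatrix(
        pd.DataFrame(
            rng.normal(size=(5000, 10)),
            index=[f"f{i}" for i in range(5000)],
            columns=[f"s{i}" for i in range(10)],
        )
    )
    design = two_group_design(10)
    fit, de = fit_and_moderate(expr, design, "group")
    df_total = fit.df_residual + fit.df_prior
    if np.isfinite(df_total):
        ks = stats.kstest(de["t"], stats.t(df_total).cdf)
    else:
        ks = stats.kstest(de["t"], stats.norm.cdf)
    assert ks.pvalue > 0.01


def test_run_contrast_against_limma_voom_oracle(tmp_path):
    """Independent oracle: the full filter->voom->moderate path agrees with
    the reference R implementation on a small unpaired contrast."""
    import subprocess

    counts, meta = sim_counts(
        10, planted=(PlantedEffect("miR-0001", "tumor_vs_normal", 2.0),), seed=12
    )
    spec = ContrastSpec("tn", ("tumor", "normal"), "compartment", "tumor", paired=False)
    de = mirc.run_contrast(counts, meta, spec).set_index("feature_id")

    sub = meta[meta["compartment"].isin(["tumor", "normal"])]
    bio = counts.subset_samples(sub["sample_id"].tolist()).drop_calibrators()
    bio.counts.to_csv(tmp_path / "counts.tsv", sep="\t")
    sub.to_csv(tmp_path / "meta.csv", index=False)
    script = tmp_path / "ref.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        suppressMessages(library(edgeR))
        args <- commandArgs(TRUE)
        x <- as.matrix(read.delim(args[1], row.names = 1, check.names = FALSE))
        meta <- read.csv(args[2])
        keep <- rowSums(cpm(x) >= 1) >= 0.5 * ncol(x)
        x <- x[keep, ]
        design <- model.matrix(~ I(meta$compartment == "tumor"))
        v <- voom(x, design)
        fit <- eBayes(lmFit(v, design))
        tab <- topTable(fit, coef = 2, number = Inf, sort.by = "none")
        write.csv(tab, args[3])
        """
    )
    out = tmp_path / "limma.csv"
    subprocess.run(
        ["Rscript", str(script), str(tmp_path / "counts.tsv"), str(tmp_path / "meta.csv"), str(out)],
        check=True,
        capture_output=True,
    )
    ref = pd.read_csv(out, index_col=0)
    shared = de.index.intersection(ref.index)
    assert len(shared) > 50
    r_lfc = np.corrcoef(de.loc[shared, "logFC"], ref.loc[shared, "logFC"])[0, 1]
    r_t = stats.spearmanr(de.loc[shared, "t"], ref.loc[shared, "t"]).statistic
    assert r_lfc > 0.99
    assert r_t > 0.95
    np.testing.assert_allclose(
        de.loc[shared, "logFC"], ref.loc[shared, "logFC"], atol=0.25
    )
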