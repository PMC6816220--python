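"""Synthetic paired-compartment small-RNA cohort generator.

Emulates the data structure of a hepatocellular-carcinoma profiling study:
matched tumor tissue, adjacent normal tissue, whole serum and serum-exosome
samples per patient (discovery + validation cohorts) plus control serum from
healthy donors, with

* negative-binomial read counts whose per-compartment RNA-class composition
  is configurable (e.g. tRNA-depleted exosomes, snoRNA-rich tissue),
* a set of spike-in calibrator RNAs added at library preparation, whose
  counts are independent of compartment, library size and sample age,
* a sample-age confounder acting as feature-specific multiplicative log2
  decay on biological (non-calibrator) features,
* planted differential-expression effects on named contrasts (the handle the
  recovery tests use), and
* an mRNA layer in which planted miRNA-target pairs are transcriptionally
  repressed, embedded in a decoy target table with weighted context scores.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import COMPARTMENTS, CountMatrix, ExprMatrix, ValidationError

CONTRASTS = (
    "tumor_vs_normal",
    "exo_vs_serum",
    "cancer_vs_control_serum",
    "HBV",
    "cirrhosis",
    "surgery",
)

#: which (compartment, positive-group) columns a contrast's effect multiplies
_CONTRAST_POSITIVE = {
    "tumor_vs_normal": lambda meta: meta["compartment"] == "tumor",
    "exo_vs_serum": lambda meta: meta["compartment"] == "exosome",
    "cancer_vs_control_serum": lambda meta: meta["compartment"] == "serum",
    "HBV": lambda meta: meta["hbv"].fillna(False).astype(bool),
    "cirrhosis": lambda meta: meta["cirrhosis"].fillna(False).astype(bool),
    "surgery": lambda meta: meta["surgery"] == "transplantation",
}

RNA_CLASS_ORDER = ("miRNA", "snoRNA", "tRNA", "scRNA", "other")

DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    # tissue: snoRNA-rich; serum/exosome: scRNA-high; exosome tRNA-depleted
    "tumor": {"miRNA": 0.55, "snoRNA": 0.20, "tRNA": 0.10, "scRNA": 0.05, "other": 0.10},
    "normal": {"miRNA": 0.55, "snoRNA": 0.20, "tRNA": 0.10, "scRNA": 0.05, "other": 0.10},
    "serum": {"miRNA": 0.45, "snoRNA": 0.05, "tRNA": 0.20, "scRNA": 0.20, "other": 0.10},
    "control_serum": {"miRNA": 0.45, "snoRNA": 0.05, "tRNA": 0.20, "scRNA": 0.20, "other": 0.10},
    "exosome": {"miRNA": 0.55, "snoRNA": 0.05, "tRNA": 0.05, "scRNA": 0.25, "other": 0.10},
}


@dataclass(frozen=True)
class PlantedEffect:
    """A known differential-expression effect injected into the cohort."""

    feature_id: str
    contrast: str
    log2fc: float
    compartment_scope: tuple[str, ...] = COMPARTMENTS

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValidationError(f"unknown contrast {self.contrast!r}")
        if not np.isfinite(self.log2fc):
            raise ValidationError("log2fc must be finite")
        bad = set(self.compartment_scope) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(f"unknown compartment(s) in scope: {sorted(bad)}")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; defaults mirror the study design."""

    n_patients_discovery: int = 17
    n_patients_validation: int = 80
    n_controls: int = 19
    n_mirna: int = 150
    n_other_ncrna: Mapping[str, int] = field(
        default_factory=lambda: {"snoRNA": 40, "tRNA": 40, "scRNA": 20, "other": 30}
    )
    n_calibrators: int = 10
    n_genes: int = 400
    nb_dispersion: float = 0.2
    lib_size_range: tuple[int, int] = (500_000, 2_000_000)
    class_composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_COMPOSITION
    )
    planted_effects: tuple[PlantedEffect, ...] = ()
    age_effect_sd: float = 0.05
    target_density: float = 0.02
    repression_slope: float = -0.7
    n_planted_targets: int = 5
    survival_beta: float = np.log(2.0)
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_calibrators < 1:
            raise ValidationError("n_calibrators must be >= 1")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if not 0 <= self.censor_rate <= 1:
            raise ValidationError("censor_rate must be in [0, 1]")
        if self.repression_slope > 0:
            raise ValidationError("repression_slope must be <= 0 (repression only)")
        if self.age_effect_sd < 0:
            raise ValidationError("age_effect_sd must be >= 0")
        for comp, comp_frac in self.class_composition.items():
            if comp not in COMPARTMENTS:
                raise ValidationError(f"unknown compartment {comp!r}")
            total = sum(comp_frac.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"class_composition[{comp!r}] sums to {total}, not 1"
                )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def default_config(**overrides) -> SimConfig:
    """Study-like defaults with planted effects analogous to the headline
    findings: one concordant onco-miR up in both tumor and exosomes (the
    miR-21 analog), one discordant feature, and one cancer-serum marker (the
    miR-122 analog, close to 4-fold up)."""
    planted = (
        PlantedEffect("miR-0001", "tumor_vs_normal", 2.0),
        PlantedEffect("miR-0001", "exo_vs_serum", 2.0),
        PlantedEffect("miR-0002", "tumor_vs_normal", 2.0),
        PlantedEffect("miR-0002", "exo_vs_serum", -2.0),
        PlantedEffect("miR-0003", "cancer_vs_control_serum", 1.95),
        PlantedEffect("miR-0004", "HBV", 1.55, ("serum",)),
    )
    cfg = SimConfig(planted_effects=planted)
    return cfg.with_(**overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# cohort


def _feature_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_mirna):
        rows.append((f"miR-{i + 1:04d}", "miRNA", False))
    for cls in ("snoRNA", "tRNA", "scRNA", "other"):
        for i in range(int(config.n_other_ncrna.get(cls, 0))):
            rows.append((f"{cls}-{i + 1:04d}", cls, False))
    for i in range(config.n_calibrators):
        rows.append((f"cal-{i + 1:02d}", "other", True))
    return pd.DataFrame(rows, columns=["feature_id", "rna_class", "is_calibrator"])


def _sample_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_pat = config.n_patients_discovery + config.n_patients_validation
    hbv = rng.random(n_pat) < 0.35
    cirr = rng.random(n_pat) < 0.5
    surgery = np.where(rng.random(n_pat) < 0.4, "transplantation", "resection")
    for p in range(n_pat):
        cohort = "discovery" if p < config.n_patients_discovery else "validation"
        pid = f"P{p + 1:03d}"
        age = rng.uniform(0.0, 10.0)
        for comp in ("tumor", "normal", "serum", "exosome"):
            rows.append(
                dict(
                    sample_id=f"{pid}_{comp}",
                    patient_id=pid,
                    compartment=comp,
                    cohort=cohort,
                    sample_age=age,
                    hbv=bool(hbv[p]),
                    cirrhosis=bool(cirr[p]),
                    surgery=surgery[p],
                )
            )
    for c in range(config.n_controls):
        rows.append(
            dict(
                sample_id=f"C{c + 1:03d}_control_serum",
                patient_id=f"C{c + 1:03d}",
                compartment="control_serum",
                cohort="discovery",
                sample_age=rng.uniform(0.0, 10.0),
                hbv=False,
                cirrhosis=False,
                surgery=pd.NA,
            )
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the full cohort count matrix plus sample metadata.

    Per-feature baseline abundances are drawn per RNA class, rescaled per
    compartment so the expected read-mass fraction of each class equals
    ``class_composition``; counts are negative binomial with the configured
    dispersion (Poisson at dispersion 0); calibrators have sample-independent
    means; sample age decays biological features; planted effects multiply
    the positive group of their contrast.
    """
    rng = np.random.default_rng(config.seed)
    feats = _feature_table(config)
    meta = _sample_table(config, rng)

    known = set(feats["feature_id"])
    for eff in config.planted_effects:
        if eff.feature_id not in known:
            raise ValidationError(f"planted feature {eff.feature_id!r} unknown")

    bio = feats[~feats["is_calibrator"]]
    n_bio = len(bio)
    # baseline relative abundance within class: heavy-tailed log-normal
    base = 2.0 ** rng.normal(5.0, 2.0, size=n_bio)
    if not np.isfinite(base).all():
        raise ValidationError("non-finite baseline means")
    cls = bio["rna_class"].to_numpy()
    class_total = {k: base[cls == k].sum() for k in RNA_CLASS_ORDER}

    # per-feature age-decay sensitivity, fixed across samples
    age_sens = rng.uniform(0.0, 1.0, size=n_bio)

    lo, hi = config.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(meta)))

    # calibrators: fixed expected counts per feature in every sample
    cal_mean = 2.0 ** rng.normal(9.0, 1.0, size=config.n_calibrators)

    # planted multiplicative effects per (feature, sample)
    effect = np.ones((n_bio, len(meta)))
    fid_index = {f: i for i, f in enumerate(bio["feature_id"])}
    for eff in config.planted_effects:
        if eff.feature_id not in fid_index:
            continue  # calibrator targeted: no biological effect
        pos = _CONTRAST_POSITIVE[eff.contrast](meta).to_numpy()
        in_scope = meta["compartment"].isin(eff.compartment_scope).to_numpy()
        effect[fid_index[eff.feature_id], pos & in_scope] *= 2.0 ** eff.log2fc

    counts = np.zeros((len(feats), len(meta)), dtype=np.int64)
    bio_rows = np.where(~feats["is_calibrator"].to_numpy())[0]
    cal_rows = np.where(feats["is_calibrator"].to_numpy())[0]
    phi = config.nb_dispersion

    for j, (_, s) in enumerate(meta.iterrows()):
        comp_frac = config.class_composition[s["compartment"]]
        scale = np.array([comp_frac.get(k, 0.0) / class_total[k] for k in cls])
        mu = base * scale
        mu = mu * effect[:, j]
        mu = mu * 2.0 ** (-config.age_effect_sd * age_sens * s["sample_age"])
        mu = mu / mu.sum() * lib[j]
        counts[bio_rows, j] = _nb_draw(rng, mu, phi)
        counts[cal_rows, j] = _nb_draw(rng, cal_mean, phi)

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=feats["feature_id"].to_numpy(), columns=meta["sample_id"].to_numpy()
        ),
        feature_class=dict(zip(feats["feature_id"], feats["rna_class"])),
        is_calibrator=dict(zip(feats["feature_id"], feats["is_calibrator"])),
    )
    return cm, meta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mu + phi*mu^2; Poisson when phi == 0."""
    if phi == 0:
        return rng.poisson(mu)
    size_param = 1.0 / phi
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


# ---------------------------------------------------------------------------
# mRNA layer


def simulate_mrna(
    config: SimConfig,
    mirna_expr: ExprMatrix,
    mirna_truth: Mapping[str, float],
    noise_sd: float = 0.3,
) -> tuple[ExprMatrix, pd.DataFrame, list[tuple[str, str]]]:
    """Simulate a log2 mRNA matrix with planted miRNA-driven repression.

    For each truth miRNA, ``n_planted_targets`` genes receive expression
    ``baseline + repression_slope * centered(log2 miRNA) + noise`` over the
    samples of ``mirna_expr``.  The returned target table holds every planted
    pair (context score drawn in U(-1, -0.45), i.e. below the -0.4 screening
    cut) plus decoy pairs sampled at ``target_density`` with scores in
    U(-1, 0).  Returns (mRNA ExprMatrix, target table, planted pair list).
    """
    if config.n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if not 0 <= config.target_density <= 1:
        raise ValidationError("target_density must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 101)
    samples = mirna_expr.sample_ids
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    base = rng.normal(8.0, 2.0, size=config.n_genes)
    expr = base[:, None] + rng.normal(0.0, 0.5, size=(config.n_genes, len(samples)))

    truth_mirnas = [m for m in mirna_truth if m in set(mirna_expr.feature_ids)]
    planted: list[tuple[str, str]] = []
    free = list(range(config.n_genes))
    rng.shuffle(free)
    for m in truth_mirnas:
        x = mirna_expr.values.loc[m].to_numpy(dtype=float)
        xc = x - x.mean()
        for _ in range(config.n_planted_targets):
            if not free:
                break
            g = free.pop()
            expr[g] = base[g] + config.repression_slope * xc + rng.normal(
                0.0, noise_sd, size=len(samples)
            )
            planted.append((m, genes[g]))

    rows = []
    planted_set = set(planted)
    for m, g in planted:
        rows.append((m, g, rng.uniform(-1.0, -0.45)))
    if config.target_density > 0:
        for m in mirna_expr.feature_ids:
            hits = rng.random(config.n_genes) < config.target_density
            for gi in np.where(hits)[0]:
                if (m, genes[gi]) not in planted_set:
                    rows.append((m, genes[gi], rng.uniform(-1.0, 0.0)))
    targets = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "weighted_context_score"])
    mrna = ExprMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), scale="log2_intensity"
    )
    return mrna, targets, planted


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    metadata: pd.DataFrame,
    group_labels: Mapping[str, int] | pd.Series,
    survival_beta: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = np.log(2.0) / 30.0,
) -> pd.DataFrame:
    """Simulate per-patient survival: exponential event times with the high
    group's hazard multiplied by ``exp(survival_beta)``, and independent
    uniform censoring calibrated to the requested marginal censoring rate.

    ``group_labels`` maps patient_id -> {0, 1}.  Times are in months.
    Returns a DataFrame (patient_id, time_months, event, group).
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series(group_labels)
    patients = labels.index.to_list()
    g = labels.to_numpy(dtype=int)
    if not set(np.unique(g)) <= {0, 1}:
        raise ValidationError("group_labels must be binary 0/1")
    haz = baseline_hazard * np.exp(survival_beta * g)
    times = rng.exponential(1.0 / haz)
    event = np.ones(len(patients), dtype=bool)
    if censor_rate > 0:
        u_max = _censor_horizon(haz, censor_rate)
        cens = rng.uniform(0.0, u_max, size=len(patients))
        event = times <= cens
        times = np.minimum(times, cens)
    return pd.DataFrame(
        {
            "patient_id": patients,
            "time_months": times,
            "event": event,
            "group": np.where(g == 1, "High", "Low"),
        }
    )


def _censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Solve for u such that C ~ U(0,u) censors the exponential mixture at
    the requested marginal rate: mean_i (1 - exp(-h_i u)) / (h_i u) = rate."""

    def marginal(u: float) -> float:
        return float(np.mean((1.0 - np.exp(-hazards * u)) / (hazards * u))) - censor_rate

    # marginal censoring prob decreases from 1 (u->0) to 0 (u->inf)
    lo, hi = 1e-9, 1.0
    while marginal(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(marginal, lo, hi)


# ---------------------------------------------------------------------------
# convenience: write all standard pipeline inputs


def write_cohort(
    outdir,
    config: SimConfig,
    counts: CountMatrix,
    metadata: pd.DataFrame,
    mrna: ExprMatrix | None = None,
    targets: pd.DataFrame | None = None,
    truth: dict | None = None,
) -> dict[str, str]:
    """Write the standard on-disk inputs; returns {artifact: path}."""
    from . import io as _mio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    _mio.write_counts(counts, outdir / "counts.tsv")
    paths["counts"] = str(outdir / "counts.tsv")
    paths["features"] = str(outdir / "counts.features.tsv")
    _mio.write_metadata(metadata, outdir / "metadata.csv")
    paths["metadata"] = str(outdir / "metadata.csv")
    if mrna is not None:
        _mio.write_expr(mrna, outdir / "mrna_expr.tsv")
        paths["mrna_expr"] = str(outdir / "mrna_expr.tsv")
    if targets is not None:
        _mio.write_targets(targets, outdir / "targets.tsv")
        paths["targets"] = str(outdir / "targets.tsv")
    if truth is not None:
        _mio.write_json(truth, outdir / "truth.json")
        paths["truth"] = str(outdir / "truth.json")
    return paths
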