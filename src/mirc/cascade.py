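"""Four-filter miRNA-target integration cascade plus gene-set enrichment.

Candidate miRNA-gene pairs from a prediction table (TargetScan-style
weighted context scores) are reduced in four ordered steps:

1. expression — keep miRNAs whose 75th-percentile log2 CPM across samples
   exceeds 10;
2. context score — keep pairs predicted strongly (score < -0.4, strict);
3. directional consistency — keep a gene only when more than 75% of its
   differentially expressed targeting miRNAs share one direction, and then
   only the majority-direction pairs;
4. anticorrelation — keep pairs whose miRNA and target mRNA are negatively
   correlated across shared samples.

The surviving gene set feeds a one-sided hypergeometric over-representation
test against user-supplied gene sets (GMT), BH-adjusted across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExprMatrix, ValidationError


@dataclass
class CascadeResult:
    retained_pairs: pd.DataFrame  # mirna_id, gene_id, weighted_context_score,
    # mirna_direction, correlation
    retained_mirnas: set[str] = field(default_factory=set)
    retained_genes: set[str] = field(default_factory=set)
    attrition: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CascadeParams:
    percentile: float = 75.0
    expr_threshold: float = 10.0
    context_cutoff: float = -0.4
    min_direction_fraction: float = 0.75
    correlation_method: str = "pearson"  # or "spearman"


def filter_mirna_expression(
    mirna_expr: ExprMatrix,
    percentile: float = 75.0,
    threshold: float = 10.0,
) -> set[str]:
    """miRNAs whose per-sample expression percentile strictly exceeds the
    threshold (default: 75th percentile > 10 log2 CPM).  Percentiles use
    linear interpolation between order statistics."""
    if mirna_expr.scale != "log2_cpm":
        raise ValidationError(
            f"expected log2_cpm expression, got scale {mirna_expr.scale!r}"
        )
    vals = mirna_expr.values
    p = np.percentile(vals.to_numpy(dtype=float), percentile, axis=1)
    return set(vals.index[p > threshold])


def filter_context_score(targets: pd.DataFrame, cutoff: float = -0.4) -> pd.DataFrame:
    """Keep pairs with weighted context score strictly below the cutoff."""
    return targets[targets["weighted_context_score"] < cutoff].reset_index(drop=True)


def filter_directional_consistency(
    targets: pd.DataFrame,
    de: pd.DataFrame,
    min_fraction: float = 0.75,
) -> pd.DataFrame:
    """Per-gene majority-direction screen over its targeting miRNAs.

    Each miRNA's direction (up/down) comes from the DE table's logFC; pairs
    whose miRNA is absent from the table are dropped with a warning.  A gene
    survives only if the fraction of its targeting miRNAs in the majority
    direction strictly exceeds ``min_fraction``; retained pairs are
    restricted to the majority direction.  Adds a ``mirna_direction``
    column.
    """
    direction = de.set_index("feature_id")["logFC"].map(
        lambda x: "up" if x > 0 else ("down" if x < 0 else None)
    )
    known = targets["mirna_id"].isin(direction.index)
    if (~known).any():
        missing = sorted(set(targets.loc[~known, "mirna_id"]))
        warnings.warn(
            f"{len(missing)} miRNA(s) absent from the DE table dropped from the "
            f"directionality filter: {missing[:5]}"
        )
    t = targets[known].copy()
    t["mirna_direction"] = direction.loc[t["mirna_id"]].to_numpy()
    t = t[t["mirna_direction"].notna()]
    kept = []
    for _, grp in t.groupby("gene_id"):
        n_up = int((grp["mirna_direction"] == "up").sum())
        n_dn = len(grp) - n_up
        majority = "up" if n_up >= n_dn else "down"
        frac = max(n_up, n_dn) / len(grp)
        if frac > min_fraction:
            kept.append(grp[grp["mirna_direction"] == majority])
    if not kept:
        return t.iloc[0:0].reset_index(drop=True)
    return pd.concat(kept).reset_index(drop=True)


def filter_anticorrelation(
    targets: pd.DataFrame,
    mirna_expr: ExprMatrix,
    mrna_expr: ExprMatrix,
    method: str = "pearson",
) -> pd.DataFrame:
    """Keep pairs whose miRNA/mRNA correlation over shared samples is < 0.

    Pairs with a missing feature or an undefined correlation (a constant
    series) are dropped with a warning.  Adds a ``correlation`` column.
    """
    shared = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("anticorrelation needs >= 3 shared samples")
    mi = mirna_expr.values[shared]
    mr = mrna_expr.values[shared]
    rows = []
    n_missing = 0
    for _, row in targets.iterrows():
        m, g = row["mirna_id"], row["gene_id"]
        if m not in mi.index or g not in mr.index:
            n_missing += 1
            continue
        x = mi.loc[m].to_numpy(dtype=float)
        y = mr.loc[g].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            n_missing += 1
            continue
        if method == "spearman":
            r = stats.spearmanr(x, y).statistic
        else:
            r = stats.pearsonr(x, y).statistic
        if r < 0:
            rows.append({**row.to_dict(), "correlation": float(r)})
    if n_missing:
        warnings.warn(
            f"{n_missing} pair(s) dropped: feature missing from expression or "
            "correlation undefined"
        )
    cols = list(targets.columns) + ["correlation"]
    return pd.DataFrame(rows, columns=cols)


def run_cascade(
    de_mirna: pd.DataFrame,
    targets: pd.DataFrame,
    mirna_expr: ExprMatrix,
    mrna_expr: ExprMatrix,
    params: CascadeParams = CascadeParams(),
) -> CascadeResult:
    """Apply the four filters in order and record per-filter attrition.

    ``de_mirna`` should already be restricted to the significant miRNAs
    whose targets are being interrogated.
    """
    attrition: dict[str, int] = {"input": len(targets)}
    de_mirnas = set(de_mirna["feature_id"])
    t = targets[targets["mirna_id"].isin(de_mirnas)].reset_index(drop=True)
    attrition["de_mirnas"] = len(t)

    if np.isfinite(params.expr_threshold):
        expressed = filter_mirna_expression(
            mirna_expr, params.percentile, params.expr_threshold
        )
        t = t[t["mirna_id"].isin(expressed)].reset_index(drop=True)
    attrition["expression"] = len(t)

    t = filter_context_score(t, params.context_cutoff)
    attrition["context_score"] = len(t)

    t = filter_directional_consistency(t, de_mirna, params.min_direction_fraction)
    attrition["directionality"] = len(t)

    t = filter_anticorrelation(t, mirna_expr, mrna_expr, params.correlation_method)
    attrition["anticorrelation"] = len(t)

    return CascadeResult(
        retained_pairs=t,
        retained_mirnas=set(t["mirna_id"]),
        retained_genes=set(t["gene_id"]),
        attrition=attrition,
    )


def enrich_gene_sets(
    genes: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation, BH across sets.

    Genes outside the universe are dropped with a warning; gene sets are
    intersected with the universe.  Returns all sets with their overlap,
    expected overlap, raw p and BH-adjusted p, plus an ``enriched`` flag at
    ``adj_p < p_cutoff``.
    """
    if not universe:
        raise ValidationError("empty universe")
    stray = genes - universe
    if stray:
        warnings.warn(f"{len(stray)} selected gene(s) outside the universe dropped")
    sel = genes & universe
    rows = []
    for name, members in gene_sets.items():
        k_set = members & universe
        overlap = sel & k_set
        # P(X >= |overlap|) for X ~ Hypergeom(|U|, |set|, |selection|)
        p = float(stats.hypergeom.sf(len(overlap) - 1, len(universe), len(k_set), len(sel)))
        rows.append(
            {
                "set": name,
                "set_size": len(k_set),
                "overlap": len(overlap),
                "expected": len(k_set) * len(sel) / len(universe),
                "p": min(p, 1.0),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "expected", "p", "overlap_genes"]
    )
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out["enriched"] = out["adj_p"] < p_cutoff
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["adj_p"] = []
        out["enriched"] = []
    return out


def de_gene_classes(
    de: pd.DataFrame, alpha: float = 0.05, lfc_cut: float = 0.5
) -> tuple[set[str], set[str]]:
    """Up-/down-regulated gene classes for enrichment: BH-adjusted p below
    ``alpha`` and log2 fold change above ``lfc_cut`` or below ``-lfc_cut``."""
    sig = de[de["adj_p"] < alpha]
    up = set(sig.loc[sig["logFC"] > lfc_cut, "feature_id"])
    down = set(sig.loc[sig["logFC"] < -lfc_cut, "feature_id"])
    return up, down
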