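"""Cross-contrast set logic and log-fold-change sign concordance.

Answers questions of the form: of the miRNAs significant in either the
tumor-vs-normal or the exosome-vs-serum comparison, how many are expressed
in every compartment, how many change in the same direction in both, and
how many are significant in both — plus direction validation of a discovery
DE table against an independent validation cohort or platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError


@dataclass
class ConcordanceResult:
    union_significant: set[str]
    expressed_in_all: set[str]
    same_sign: set[str]
    both_significant: set[str]
    both_significant_same_sign: set[str]
    logfc_pairs: pd.DataFrame  # index feature_id, columns logFC_A / logFC_B
    pearson_r: float | None = None

    def __post_init__(self) -> None:
        assert self.both_significant_same_sign <= self.both_significant
        assert self.both_significant <= self.union_significant
        assert self.same_sign <= self.expressed_in_all

    def counts(self) -> dict[str, int]:
        return {
            "union_significant": len(self.union_significant),
            "expressed_in_all": len(self.expressed_in_all),
            "same_sign": len(self.same_sign),
            "both_significant": len(self.both_significant),
            "both_significant_same_sign": len(self.both_significant_same_sign),
        }


def _sig_set(de: pd.DataFrame, alpha: float) -> set[str]:
    return set(de.loc[de["adj_p"] < alpha, "feature_id"])


def _lfc(de: pd.DataFrame) -> pd.Series:
    return de.set_index("feature_id")["logFC"]


def compare_contrasts(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    expressed: list[set[str]] | None = None,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Set comparison of two DE tables.

    * union_significant: adj_p < alpha in A or B;
    * expressed_in_all: the union-significant features present in every
      supplied per-sample-type expressed set (all features if none given);
    * same_sign: of those, features whose logFC signs agree and are nonzero
      in both tables (a zero logFC carries no direction);
    * both_significant / both_significant_same_sign: significant in both,
      and additionally sign-concordant;
    * pearson_r: correlation of (logFC_A, logFC_B) over both_significant,
      absent (None) with fewer than 3 pairs.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    sig_a, sig_b = _sig_set(de_a, alpha), _sig_set(de_b, alpha)
    union = sig_a | sig_b
    in_all = set(union)
    for s in expressed or []:
        in_all &= set(s)
    lfc_a, lfc_b = _lfc(de_a), _lfc(de_b)
    in_both_tables = in_all & set(lfc_a.index) & set(lfc_b.index)
    same_sign = {
        f
        for f in in_both_tables
        if np.sign(lfc_a[f]) == np.sign(lfc_b[f]) and np.sign(lfc_a[f]) != 0
    }
    both_sig = sig_a & sig_b & in_all
    both_sig_same = both_sig & same_sign
    pairs = pd.DataFrame(
        {
            "logFC_A": lfc_a.reindex(sorted(both_sig)),
            "logFC_B": lfc_b.reindex(sorted(both_sig)),
        }
    )
    r = None
    if len(pairs) >= 3:
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(pairs["logFC_A"], pairs["logFC_B"])[0, 1])
        if not np.isfinite(r):
            r = None
    return ConcordanceResult(
        union_significant=union,
        expressed_in_all=in_all,
        same_sign=same_sign,
        both_significant=both_sig,
        both_significant_same_sign=both_sig_same,
        logfc_pairs=pairs,
        pearson_r=r,
    )


def validate_directions(
    de_discovery: pd.DataFrame,
    de_validation: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[int, int, float | None]:
    """Direction consistency of discovery-significant features in validation.

    Evaluable features are significant in discovery and present in the
    validation table (undetected features drop out of the denominator);
    consistent features keep their logFC sign.  Returns (n_evaluable,
    n_consistent, fraction) with fraction None when nothing is evaluable.
    """
    sig = _sig_set(de_discovery, alpha)
    lfc_d, lfc_v = _lfc(de_discovery), _lfc(de_validation)
    evaluable = sorted(sig & set(lfc_v.index))
    consistent = [
        f
        for f in evaluable
        if np.sign(lfc_d[f]) == np.sign(lfc_v[f]) and np.sign(lfc_d[f]) != 0
    ]
    n_eval = len(evaluable)
    frac = len(consistent) / n_eval if n_eval else None
    return n_eval, len(consistent), frac
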