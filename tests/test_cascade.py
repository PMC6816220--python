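"""The four-filter target cascade and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirc
from mirc.cascade import (
    CascadeParams,
    de_gene_classes,
    enrich_gene_sets,
    filter_anticorrelation,
    filter_context_score,
    filter_directional_consistency,
    filter_mirna_expression,
    run_cascade,
)
from mirc.io import ExprMatrix, ValidationError
from tests.conftest import make_de


def expr_of(rows: dict, samples=None, scale="log2_cpm"):
    df = pd.DataFrame(rows).T
    if samples is not None:
        df.columns = samples
    return ExprMatrix(df.astype(float), scale=scale)


def targets_of(triples):
    return pd.DataFrame(
        triples, columns=["mirna_id", "gene_id", "weighted_context_score"]
    )


# --- expression filter ----------------------------------------------------


def test_percentile_interpolated_hand_value():
    e = expr_of({"m1": [8, 9, 10, 11]})
    # P75 of (8,9,10,11) by linear interpolation = 10.25 > 10
    assert filter_mirna_expression(e) == {"m1"}


def test_percentile_boundary_strict():
    e = expr_of({"m1": [10, 10, 10, 10], "m2": [12, 12, 12, 12]})
    assert filter_mirna_expression(e) == {"m2"}


def test_expression_filter_rejects_wrong_scale():
    e = expr_of({"m1": [12, 12]}, scale="log2_intensity")
    with pytest.raises(ValidationError, match="scale"):
        filter_mirna_expression(e)


# --- context score --------------------------------------------------------


@pytest.mark.parametrize(
    "score,kept", [(-0.41, True), (-0.4, False), (-0.39, False), (-1.0, True)]
)
def test_context_score_strict_boundary(score, kept):
    t = targets_of([("m1", "g1", score)])
    out = filter_context_score(t)
    assert (len(out) == 1) is kept


def test_context_score_empty_table():
    out = filter_context_score(targets_of([]))
    assert out.empty


# --- directionality -------------------------------------------------------


def de_updown():
    return make_de(
        [("u1", 1.0, 0.01), ("u2", 2.0, 0.01), ("u3", 1.0, 0.01), ("u4", 1.5, 0.01),
         ("d1", -1.0, 0.01)]
    )


def test_direction_three_of_four_dropped():
    t = targets_of([("u1", "g", -0.5), ("u2", "g", -0.5), ("u3", "g", -0.5), ("d1", "g", -0.5)])
    out = filter_directional_consistency(t, de_updown())
    assert out.empty  # 3/4 = 0.75, not > 0.75


def test_direction_all_up_kept():
    t = targets_of([(m, "g", -0.5) for m in ("u1", "u2", "u3", "u4")])
    out = filter_directional_consistency(t, de_updown())
    assert len(out) == 4 and (out["mirna_direction"] == "up").all()


def test_direction_four_of_five_keeps_majority_pairs():
    t = targets_of([(m, "g", -0.5) for m in ("u1", "u2", "u3", "u4", "d1")])
    out = filter_directional_consistency(t, de_updown())
    assert set(out["mirna_id"]) == {"u1", "u2", "u3", "u4"}


def test_direction_unknown_mirna_dropped_with_warning():
    t = targets_of([("u1", "g", -0.5), ("mystery", "g2", -0.5)])
    with pytest.warns(UserWarning, match="absent"):
        out = filter_directional_consistency(t, de_updown())
    assert set(out["mirna_id"]) == {"u1"}


# --- anticorrelation ------------------------------------------------------


def test_anticorrelation_keeps_planted_drops_positive_and_constant():
    rng = np.random.default_rng(0)
    x = rng.normal(10, 1, 30)
    samples = [f"s{i}" for i in range(30)]
    mi = expr_of({"m1": x}, samples)
    mr = ExprMatrix(
        pd.DataFrame(
            {
                "anti": 8 - x + rng.normal(0, 0.1, 30),
                "pos": 2 * x + 1.0,
                "flat": np.full(30, 5.0),
            }
        ).T.set_axis(samples, axis=1)
    )
    t = targets_of([("m1", "anti", -0.5), ("m1", "pos", -0.5), ("m1", "flat", -0.5)])
    with pytest.warns(UserWarning):
        out = filter_anticorrelation(t, mi, mr)
    assert list(out["gene_id"]) == ["anti"]
    assert out["correlation"].iloc[0] < -0.9


def test_anticorrelation_needs_shared_samples():
    mi = expr_of({"m1": [1, 2]}, ["a", "b"])
    mr = expr_of({"g1": [1, 2]}, ["c", "d"], scale="log2_intensity")
    with pytest.raises(ValidationError, match="shared"):
        filter_anticorrelation(targets_of([("m1", "g1", -0.5)]), mi, mr)


# --- full cascade ---------------------------------------------------------


def cascade_scenario(seed=0, n_decoys_mirnas=20, n_genes=300):
    """4 high-expressed DE miRNAs each repressing 3 genes; decoy pairs with
    random scores and uncorrelated genes."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(40)]
    mirnas = [f"mir{i}" for i in range(n_decoys_mirnas)]
    truth = mirnas[:4]
    mi = ExprMatrix(
        pd.DataFrame(
            rng.normal(12, 1.2, size=(n_decoys_mirnas, 40)), index=mirnas, columns=samples
        )
    )
    genes = [f"g{i}" for i in range(n_genes)]
    G = rng.normal(8, 1, size=(n_genes, 40))
    planted = []
    gi = 0
    for m in truth:
        for _ in range(3):
            G[gi] = 8 - 0.8 * (mi.values.loc[m] - 12) + rng.normal(0, 0.2, 40)
            planted.append((m, genes[gi]))
            gi += 1
    mr = ExprMatrix(pd.DataFrame(G, index=genes, columns=samples), scale="log2_intensity")
    rows = [(m, g, rng.uniform(-1, -0.45)) for m, g in planted]
    for m in mirnas:
        for g in rng.choice(genes[gi:], size=8, replace=False):
            rows.append((m, g, rng.uniform(-1, 0)))
    de = make_de([(m, 1.0 if i % 2 == 0 else -1.0, 0.01) for i, m in enumerate(mirnas)])
    return de, targets_of(rows), mi, mr, planted


def test_cascade_recovers_planted_pairs():
    de, targets, mi, mr, planted = cascade_scenario()
    res = run_cascade(de, targets, mi, mr)
    got = set(zip(res.retained_pairs["mirna_id"], res.retained_pairs["gene_id"]))
    recall = len(got & set(planted)) / len(planted)
    assert recall >= 0.9
    assert (res.retained_pairs["correlation"] < 0).all()
    attr = list(res.attrition.values())
    assert all(a >= b for a, b in zip(attr, attr[1:]))


def test_cascade_row_order_invariant():
    de, targets, mi, mr, _ = cascade_scenario(seed=1)
    res1 = run_cascade(de, targets, mi, mr)
    shuffled = targets.sample(frac=1.0, random_state=7).reset_index(drop=True)
    res2 = run_cascade(de, shuffled, mi, mr)
    key = lambda r: set(zip(r["mirna_id"], r["gene_id"]))
    assert key(res1.retained_pairs) == key(res2.retained_pairs)


def test_cascade_filters_disabled_leaves_anticorrelation_only():
    de, targets, mi, mr, _ = cascade_scenario(seed=2)
    params = CascadeParams(
        expr_threshold=-np.inf, context_cutoff=0.0, min_direction_fraction=0.0
    )
    res = run_cascade(de, targets, mi, mr, params)
    # every retained pair is negatively correlated; nothing else filtered
    direct = filter_anticorrelation(
        filter_directional_consistency(
            targets[targets["weighted_context_score"] < 0.0], de, 0.0
        ),
        mi,
        mr,
    )
    assert len(res.retained_pairs) == len(direct)


def test_cascade_empty_de_empty_result():
    de, targets, mi, mr, _ = cascade_scenario(seed=3)
    res = run_cascade(de.iloc[0:0], targets, mi, mr)
    assert res.retained_pairs.empty
    assert res.retained_mirnas == set() and res.retained_genes == set()


def test_expression_and_context_filters_commute():
    de, targets, mi, mr, _ = cascade_scenario(seed=4)
    expressed = filter_mirna_expression(mi, 75, 10)
    a = filter_context_score(
        targets[targets["mirna_id"].isin(expressed)].reset_index(drop=True)
    )
    b = filter_context_score(targets)
    b = b[b["mirna_id"].isin(expressed)].reset_index(drop=True)
    key = lambda t: set(zip(t["mirna_id"], t["gene_id"]))
    assert key(a) == key(b)


def test_null_anticorrelation_passes_about_half():
    """Without planted repression, roughly half of candidate pairs survive
    the r < 0 filter (it is a weak filter on its own)."""
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(30)]
    mirnas = [f"m{i}" for i in range(25)]
    genes = [f"g{i}" for i in range(25)]
    mi = ExprMatrix(pd.DataFrame(rng.normal(12, 1, (25, 30)), index=mirnas, columns=samples))
    mr = ExprMatrix(
        pd.DataFrame(rng.normal(8, 1, (25, 30)), index=genes, columns=samples),
        scale="log2_intensity",
    )
    pairs = targets_of([(m, g, -0.5) for m in mirnas for g in genes])  # 625 pairs
    out = filter_anticorrelation(pairs, mi, mr)
    frac = len(out) / len(pairs)
    ci = 2.6 * np.sqrt(0.25 / len(pairs))
    assert abs(frac - 0.5) < ci + 0.02


# --- enrichment -----------------------------------------------------------


def test_hypergeometric_hand_value():
    universe = {f"g{i}" for i in range(20)}
    geneset = {f"g{i}" for i in range(5)}
    selected = set(geneset)
    out = enrich_gene_sets(selected, universe, {"S": geneset}, p_cutoff=0.01)
    assert out["p"].iloc[0] == pytest.approx(1.0 / 15504.0, abs=1e-12)


def test_enrichment_genes_equal_universe_no_signal():
    universe = {f"g{i}" for i in range(30)}
    sets = {"A": {f"g{i}" for i in range(10)}, "B": {f"g{i}" for i in range(5, 25)}}
    out = enrich_gene_sets(set(universe), universe, sets)
    assert (out["p"] == 1.0).all()
    assert not out["enriched"].any()


def test_enrichment_empty_selection():
    universe = {f"g{i}" for i in range(10)}
    out = enrich_gene_sets(set(), universe, {"A": {"g1"}})
    assert (out["overlap"] == 0).all()
    assert not out["enriched"].any()


def test_enrichment_empty_universe_errors():
    with pytest.raises(ValidationError):
        enrich_gene_sets({"g1"}, set(), {"A": {"g1"}})


def test_enrichment_stray_genes_warn_and_drop():
    universe = {"g1", "g2", "g3", "g4"}
    with pytest.warns(UserWarning, match="outside the universe"):
        out = enrich_gene_sets({"g1", "zz"}, universe, {"A": {"g1", "g2"}})
    assert out["overlap"].iloc[0] == 1


def test_enrichment_matches_fisher_exact():
    rng = np.random.default_rng(6)
    universe = {f"g{i}" for i in range(200)}
    sel = set(rng.choice(sorted(universe), 40, replace=False))
    gs = {f"S{j}": set(rng.choice(sorted(universe), 30, replace=False)) for j in range(5)}
    out = enrich_gene_sets(sel, universe, gs).set_index("set")
    for name, members in gs.items():
        a = len(sel & members)
        table = [
            [a, len(sel) - a],
            [len(members) - a, len(universe) - len(sel) - len(members) + a],
        ]
        p_ref = stats.fisher_exact(table, alternative="greater").pvalue
        assert out.loc[name, "p"] == pytest.approx(p_ref, rel=1e-9)


def test_de_gene_classes_thresholds():
    de = make_de(
        [("a", 0.6, 0.01), ("b", 0.4, 0.01), ("c", -0.7, 0.01), ("d", 0.9, 0.2)]
    )
    up, down = de_gene_classes(de)
    assert up == {"a"} and down == {"c"}
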