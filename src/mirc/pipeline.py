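"""Config-driven orchestration: simulate or ingest, normalize, run the DE
contrasts, concordance, the target cascade, and the survival screen, with a
JSON run manifest recording every output file's content hash.

Reruns with the same config and seed produce byte-identical outputs and
therefore identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .cascade import CascadeParams, run_cascade
from .concordance import compare_contrasts, validate_directions
from .diffexpr import STANDARD_CONTRASTS, clinical_contrast, run_contrast
from .io import ValidationError
from .normalize import calibrator_size_factors, cpm, filter_expressed
from .simulate import SimConfig, default_config, simulate_cohort, simulate_mrna, simulate_survival
from .survival import survival_screen

log = logging.getLogger("mirc")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a mapping")
    return cfg


def _sim_config_from_block(block: dict, seed: int | None) -> SimConfig:
    from .simulate import PlantedEffect

    block = dict(block or {})
    planted = block.pop("planted_effects", None)
    if seed is not None:
        block["seed"] = seed
    if planted is not None:
        block["planted_effects"] = tuple(
            PlantedEffect(
                p["feature_id"],
                p["contrast"],
                float(p["log2fc"]),
                tuple(p.get("compartment_scope", mio.COMPARTMENTS)),
            )
            for p in planted
        )
        return default_config().with_(**block)
    return default_config(**block)


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the full analysis; returns the manifest (also written to
    ``outdir/manifest.json``).

    ``config`` may contain a ``simulate`` block (SimConfig fields) or
    explicit ``counts``/``metadata`` paths, a ``contrasts`` list, and a
    ``thresholds`` mapping (alpha, min_cpm, min_fraction, percentile,
    context_cutoff, direction_fraction, enrichment_cutoff).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO, format="%(asctime)s %(name)s: %(message)s"
    )
    thresholds = {
        "alpha": 0.05,
        "min_cpm": 1.0,
        "min_fraction": 0.5,
        "percentile": 75.0,
        "expr_threshold": 10.0,
        "context_cutoff": -0.4,
        "direction_fraction": 0.75,
        "enrichment_cutoff": 0.01,
        **(config.get("thresholds") or {}),
    }
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": thresholds,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
        manifest["stages"].setdefault(stage, []).append(name)

    # --- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        mrna = targets = truth_pairs = None
        if "simulate" in config or ("counts" not in config.get("inputs", config)):
            if "simulate" not in config:
                raise ValidationError(
                    "config needs either a 'simulate' block or a 'counts' input path"
                )
            sim_cfg = _sim_config_from_block(config["simulate"], seed)
            log.info("simulating cohort (seed=%s)", sim_cfg.seed)
            counts, metadata = simulate_cohort(sim_cfg)
            tumor_samples = metadata.loc[
                metadata["compartment"] == "tumor", "sample_id"
            ].tolist()
            mirna_mask = [
                counts.feature_class[f] == "miRNA" for f in counts.feature_ids
            ]
            tumor_expr = cpm(counts.subset_samples(tumor_samples), log=True)
            mirna_expr_t = mio.ExprMatrix(
                tumor_expr.values.loc[np.array(mirna_mask)[~counts.calibrator_mask()]],
                scale="log2_cpm",
            )
            truth = {
                e.feature_id: e.log2fc
                for e in sim_cfg.planted_effects
                if e.contrast == "tumor_vs_normal"
            }
            mrna, targets, truth_pairs = simulate_mrna(sim_cfg, mirna_expr_t, truth)
            paths = mio.write_counts(counts, outdir / "counts.tsv")
            record(stage, "counts", outdir / "counts.tsv")
            record(stage, "features", outdir / "counts.features.tsv")
            mio.write_metadata(metadata, outdir / "metadata.csv")
            record(stage, "metadata", outdir / "metadata.csv")
            mio.write_expr(mrna, outdir / "mrna_expr.tsv")
            record(stage, "mrna_expr", outdir / "mrna_expr.tsv")
            mio.write_targets(targets, outdir / "targets.tsv")
            record(stage, "targets", outdir / "targets.tsv")
            mio.write_json(
                {"planted_effects": [asdict(e) for e in sim_cfg.planted_effects],
                 "planted_pairs": truth_pairs},
                outdir / "truth.json",
            )
            record(stage, "truth", outdir / "truth.json")
        else:
            inputs = config.get("inputs", config)
            counts = mio.read_counts(inputs["counts"], inputs.get("features"))
            metadata = mio.read_metadata(inputs["metadata"])
            if "mrna_expr" in inputs:
                mrna = mio.read_expr(inputs["mrna_expr"])
            if "targets" in inputs:
                targets = mio.read_targets(inputs["targets"])
    except Exception:
        log.error("stage %r failed", stage)
        _write_manifest(manifest, outdir)
        raise

    # --- stage: normalize --------------------------------------------------
    stage = "normalize"
    try:
        sf = calibrator_size_factors(counts)
        sf.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
        record(stage, "size_factors", outdir / "size_factors.tsv")
        expr_all = cpm(counts, log=True, size_factors=sf)
        mio.write_expr(expr_all, outdir / "log2cpm.tsv")
        record(stage, "log2cpm", outdir / "log2cpm.tsv")
    except Exception:
        log.error("stage %r failed", stage)
        _write_manifest(manifest, outdir)
        raise

    # --- stage: differential expression ------------------------------------
    stage = "de"
    de_tables: dict[str, pd.DataFrame] = {}
    contrast_names = config.get(
        "contrasts", ["tumor_vs_normal", "exo_vs_serum", "cancer_vs_control_serum"]
    )
    try:
        for cname in contrast_names:
            if isinstance(cname, dict):
                spec = clinical_contrast(
                    cname["comparison"],
                    cname["compartment"],
                    tuple(cname.get("adjust_for", ("sample_age",))),
                )
            else:
                spec = STANDARD_CONTRASTS[cname]
            log.info("contrast %s", spec.name)
            de = run_contrast(
                counts,
                metadata,
                spec,
                alpha=thresholds["alpha"],
                min_cpm=thresholds["min_cpm"],
                min_fraction=thresholds["min_fraction"],
                size_factors=sf,
            )
            de_tables[spec.name] = de
            mio.write_de(de, outdir / f"de_{spec.name}.tsv")
            record(stage, f"de_{spec.name}", outdir / f"de_{spec.name}.tsv")
    except Exception:
        log.error("stage %r failed", stage)
        _write_manifest(manifest, outdir)
        raise

    # --- stage: concordance -------------------------------------------------
    stage = "concordance"
    try:
        if {"tumor_vs_normal", "exo_vs_serum"} <= set(de_tables):
            expressed_sets = []
            for comp in ("tumor", "normal", "serum", "exosome"):
                samp = metadata.loc[metadata["compartment"] == comp, "sample_id"]
                samp = [s for s in samp if s in set(counts.sample_ids)]
                if samp:
                    kept = filter_expressed(
                        counts.subset_samples(samp),
                        thresholds["min_cpm"],
                        thresholds["min_fraction"],
                    )
                    expressed_sets.append(set(kept.feature_ids))
            res = compare_contrasts(
                de_tables["tumor_vs_normal"],
                de_tables["exo_vs_serum"],
                expressed_sets,
                alpha=thresholds["alpha"],
            )
            payload = {k: sorted(v) for k, v in (
                ("union_significant", res.union_significant),
                ("expressed_in_all", res.expressed_in_all),
                ("same_sign", res.same_sign),
                ("both_significant", res.both_significant),
                ("both_significant_same_sign", res.both_significant_same_sign),
            )}
            payload["counts"] = res.counts()
            payload["pearson_r"] = res.pearson_r
            mio.write_json(payload, outdir / "concordance.json")
            record(stage, "concordance", outdir / "concordance.json")
    except Exception:
        log.error("stage %r failed", stage)
        _write_manifest(manifest, outdir)
        raise

    # --- stage: cascade -----------------------------------------------------
    stage = "cascade"
    try:
        if targets is not None and mrna is not None and "tumor_vs_normal" in de_tables:
            de_sig = de_tables["tumor_vs_normal"]
            de_sig = de_sig[de_sig["adj_p"] < thresholds["alpha"]]
            tumor_samples = [
                s for s in metadata.loc[metadata["compartment"] == "tumor", "sample_id"]
                if s in set(counts.sample_ids)
            ]
            mi_expr = cpm(counts.subset_samples(tumor_samples), log=True, size_factors=sf.reindex(tumor_samples))
            mi_expr = mio.ExprMatrix(
                mi_expr.values.loc[[f for f in mi_expr.feature_ids
                                    if counts.feature_class[f] in ("miRNA", "isomiR")]],
                scale="log2_cpm",
            )
            result = run_cascade(
                de_sig,
                targets,
                mi_expr,
                mrna,
                CascadeParams(
                    percentile=thresholds["percentile"],
                    expr_threshold=thresholds["expr_threshold"],
                    context_cutoff=thresholds["context_cutoff"],
                    min_direction_fraction=thresholds["direction_fraction"],
                ),
            )
            result.retained_pairs.to_csv(outdir / "cascade_pairs.tsv", sep="\t", index=False)
            record(stage, "cascade_pairs", outdir / "cascade_pairs.tsv")
            mio.write_json(result.attrition, outdir / "cascade_attrition.json")
            record(stage, "cascade_attrition", outdir / "cascade_attrition.json")
    except Exception:
        log.error("stage %r failed", stage)
        _write_manifest(manifest, outdir)
        raise

    # --- stage: survival ----------------------------------------------------
    stage = "survival"
    try:
        if "simulate" in config:
            # derive a survival table tied to the miR-21-analog tumor expression
            sim_cfg = _sim_config_from_block(config["simulate"], seed)
            tumor = metadata[metadata["compartment"] == "tumor"].set_index("patient_id")
            planted_up = next(
                (e.feature_id for e in sim_cfg.planted_effects
                 if e.contrast == "tumor_vs_normal" and e.log2fc > 0),
                None,
            )
            tumor_expr = cpm(
                counts.subset_samples(tumor["sample_id"].tolist()), log=True
            )
            tumor_expr.values.columns = tumor.index  # patient ids
            anchor = planted_up or tumor_expr.feature_ids[0]
            groups = (
                tumor_expr.values.loc[anchor]
                > tumor_expr.values.loc[anchor].median()
            ).astype(int)
            surv = simulate_survival(
                metadata,
                groups,
                sim_cfg.survival_beta,
                sim_cfg.censor_rate,
                seed=(sim_cfg.seed + 7) % (2**31),
            )
            surv.to_csv(outdir / "survival.csv", index=False)
            record(stage, "survival_data", outdir / "survival.csv")
            screen = survival_screen(
                mio.ExprMatrix(tumor_expr.values, scale="log2_cpm"), surv
            )
            screen.to_csv(outdir / "survival_screen.tsv", sep="\t", index=False)
            record(stage, "survival_screen", outdir / "survival_screen.tsv")
        elif "survival" in config.get("inputs", {}):
            surv = pd.read_csv(config["inputs"]["survival"])
            screen = survival_screen(expr_all, surv)
            screen.to_csv(outdir / "survival_screen.tsv", sep="\t", index=False)
            record(stage, "survival_screen", outdir / "survival_screen.tsv")
    except Exception:
        log.error("stage %r failed", stage)
        _write_manifest(manifest, outdir)
        raise

    _write_manifest(manifest, outdir)
    log.info("pipeline complete: %d outputs", len(manifest["outputs"]))
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
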