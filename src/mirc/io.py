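"""Readers and writers for the pipeline's on-disk artifacts.

All tabular artifacts are plain text: counts and annotation as TSV (a
MatrixMarket triplet with sidecar id files is accepted for sparse counts),
sample metadata and survival tables as CSV, gene sets as GMT, configuration
and truth records as JSON/YAML.  Readers validate strictly and reject rather
than coerce malformed input; every writer emits files its reader accepts.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RNA_CLASSES = ("miRNA", "isomiR", "snoRNA", "tRNA", "scRNA", "other")
COMPARTMENTS = ("tumor", "normal", "serum", "exosome", "control_serum")
COHORTS = ("discovery", "validation")
SURGERY_TYPES = ("resection", "transplantation")


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates its contract."""


@dataclass
class CountMatrix:
    """Integer feature-by-sample read counts with per-feature annotation.

    ``counts`` is a features x samples DataFrame of nonnegative integers;
    ``feature_class`` maps every feature id to one of the small-RNA classes
    (miRNA, isomiR, snoRNA, tRNA, scRNA, other) and ``is_calibrator`` flags
    the spike-in calibrator features that are excluded from library sizes.
    """

    counts: pd.DataFrame
    feature_class: dict[str, str]
    is_calibrator: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts.index.name = "feature_id"
        idx = self.counts.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = idx[np.where(~np.isclose(arr, np.round(arr)))[0][0]]
                raise ValidationError(f"non-integer count in feature {bad!r}")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = idx[np.where((arr < 0).any(axis=1))[0][0]]
            raise ValidationError(f"negative count in feature {bad!r}")
        missing = [f for f in idx if f not in self.feature_class]
        if missing:
            raise ValidationError(f"features without RNA class: {missing[:5]}")
        bad_cls = {f: c for f, c in self.feature_class.items() if c not in RNA_CLASSES}
        if bad_cls:
            raise ValidationError(f"unknown RNA class: {bad_cls}")
        for f in idx:
            self.is_calibrator.setdefault(f, False)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def calibrator_mask(self) -> np.ndarray:
        return np.array([self.is_calibrator[f] for f in self.counts.index], dtype=bool)

    def class_array(self) -> np.ndarray:
        return np.array([self.feature_class[f] for f in self.counts.index])

    def drop_calibrators(self) -> "CountMatrix":
        keep = ~self.calibrator_mask()
        sub = self.counts.loc[keep]
        return CountMatrix(
            counts=sub.copy(),
            feature_class={f: self.feature_class[f] for f in sub.index},
            is_calibrator={f: False for f in sub.index},
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        cols = list(sample_ids)
        missing = [s for s in cols if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return CountMatrix(
            counts=self.counts[cols].copy(),
            feature_class=dict(self.feature_class),
            is_calibrator=dict(self.is_calibrator),
        )


@dataclass
class ExprMatrix:
    """Real-valued feature-by-sample expression on a declared scale.

    ``scale`` is ``log2_cpm`` for sequencing-derived values or
    ``log2_intensity`` for array-like data; ``weights``, when present, holds
    strictly positive per-observation precision weights of the same shape.
    """

    values: pd.DataFrame
    scale: str = "log2_cpm"
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values.index.name = "feature_id"
        if self.scale not in ("log2_cpm", "log2_intensity", "cpm"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite expression values")
        if self.weights is not None:
            if self.weights.shape != self.values.shape:
                raise ValidationError("weights shape mismatch")
            if (self.weights.to_numpy() <= 0).any():
                raise ValidationError("non-positive weights")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


REQUIRED_META_COLS = ("sample_id", "compartment", "cohort", "sample_age")
OPTIONAL_META_COLS = (
    "patient_id",
    "hbv",
    "cirrhosis",
    "surgery",
    "survival_time_months",
    "event",
)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and normalise its dtypes.

    Missing clinical values stay missing (NA), never imputed.
    """
    for col in REQUIRED_META_COLS:
        if col not in df.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad = set(df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValidationError(f"unknown compartment level(s): {sorted(bad)}")
    bad = set(df["cohort"].dropna()) - set(COHORTS)
    if bad:
        raise ValidationError(f"unknown cohort level(s): {sorted(bad)}")
    if "surgery" in df.columns:
        bad = set(df["surgery"].dropna()) - set(SURGERY_TYPES)
        if bad:
            raise ValidationError(f"unknown surgery level(s): {sorted(bad)}")
    df = df.copy()
    df["sample_age"] = pd.to_numeric(df["sample_age"])
    for col in ("hbv", "cirrhosis", "event"):
        if col in df.columns and df[col].notna().any():
            vals = df[col].dropna().astype(str).str.lower()
            ok = vals.isin(["true", "false", "1", "0", "1.0", "0.0"])
            if not ok.all():
                raise ValidationError(f"column {col!r} must be boolean")
            df[col] = df[col].map(
                lambda v: pd.NA
                if pd.isna(v)
                else str(v).lower() in ("true", "1", "1.0")
            )
    if "survival_time_months" in df.columns:
        t = pd.to_numeric(df["survival_time_months"], errors="coerce")
        if (t.dropna() < 0).any():
            raise ValidationError("negative survival_time_months")
        df["survival_time_months"] = t
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# counts


def write_counts(cm: CountMatrix, path: str | Path, annotation_path: str | Path | None = None) -> None:
    """Write counts as TSV plus a feature-annotation sidecar TSV.

    The sidecar defaults to ``<path stem>.features.tsv`` next to the counts.
    """
    path = Path(path)
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")
    ann = pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "rna_class": [cm.feature_class[f] for f in cm.feature_ids],
            "is_calibrator": [cm.is_calibrator[f] for f in cm.feature_ids],
        }
    )
    if annotation_path is None:
        annotation_path = path.with_suffix("").with_suffix(".features.tsv")
    ann.to_csv(annotation_path, sep="\t", index=False)


def _read_annotation(path: Path) -> tuple[dict[str, str], dict[str, bool]]:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("feature_id", "rna_class"):
        if col not in ann.columns:
            raise ValidationError(f"annotation missing column {col!r}")
    if ann["feature_id"].duplicated().any():
        raise ValidationError("duplicate feature_id in annotation")
    classes = dict(zip(ann["feature_id"], ann["rna_class"]))
    if "is_calibrator" in ann.columns:
        cal = {
            f: str(v).lower() in ("true", "1", "1.0")
            for f, v in zip(ann["feature_id"], ann["is_calibrator"])
        }
    else:
        cal = {f: False for f in ann["feature_id"]}
    return classes, cal


def read_counts(path: str | Path, annotation_path: str | Path | None = None) -> CountMatrix:
    """Read a counts TSV (or MatrixMarket triplet) and its annotation sidecar.

    For MatrixMarket input pass the ``.mtx`` path; ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` must hold the feature and sample ids, one per line.
    """
    path = Path(path)
    if annotation_path is None:
        annotation_path = path.with_suffix("").with_suffix(".features.tsv")
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        rows = Path(str(path)[: -len(".mtx")] + ".rows.txt").read_text().split()
        cols = Path(str(path)[: -len(".mtx")] + ".cols.txt").read_text().split()
        if mat.shape != (len(rows), len(cols)):
            raise ValidationError("MatrixMarket shape does not match id files")
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = "feature_id"
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad_rows = df.index[
            ~df.apply(lambda r: pd.to_numeric(r, errors="coerce").notna().all(), axis=1)
        ]
        raise ValidationError(f"non-numeric counts in feature {bad_rows[0]!r}")
    neg = (arr < 0).any(axis=1)
    if neg.any():
        raise ValidationError(f"negative count in feature {df.index[neg][0]!r}")
    if not np.allclose(arr, np.round(arr)):
        frac = ~np.isclose(arr, np.round(arr))
        raise ValidationError(
            f"non-integer count in feature {df.index[frac.any(axis=1)][0]!r}"
        )
    classes, cal = _read_annotation(Path(annotation_path))
    return CountMatrix(df.astype(np.int64), classes, cal)


# ---------------------------------------------------------------------------
# metadata / targets / expression / GMT / DE tables


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    return validate_metadata(df)


def write_targets(targets: pd.DataFrame, path: str | Path) -> None:
    targets.to_csv(path, sep="\t", index=False)


def read_targets(path: str | Path) -> pd.DataFrame:
    """Read a miRNA-to-gene target table with weighted context scores."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    for col in ("mirna_id", "gene_id", "weighted_context_score"):
        if col not in df.columns:
            raise ValidationError(f"target table missing column {col!r}")
    if df.duplicated(subset=["mirna_id", "gene_id"]).any():
        dup = df[df.duplicated(subset=["mirna_id", "gene_id"])].iloc[0]
        raise ValidationError(
            f"duplicate target pair ({dup['mirna_id']}, {dup['gene_id']})"
        )
    if not np.isfinite(df["weighted_context_score"].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite weighted_context_score")
    return df


def write_expr(expr: ExprMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = f"feature_id[{expr.scale}]"
    df.to_csv(path, sep="\t")


def read_expr(path: str | Path, scale: str | None = None) -> ExprMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    name = df.index.name or ""
    if scale is None:
        scale = name[name.find("[") + 1 : name.find("]")] if "[" in name else "log2_cpm"
    df.index.name = "feature_id"
    return ExprMatrix(df, scale=scale)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: name, description, then members."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line {lineno}: fewer than 3 fields")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"GMT duplicate set name {name!r}")
        sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


DE_COLUMNS = ("feature_id", "logFC", "aveExpr", "t", "p", "adj_p")


def write_de(de: pd.DataFrame, path: str | Path) -> None:
    de.reset_index(drop=True).to_csv(path, sep="\t", index=False, columns=list(DE_COLUMNS))


def read_de(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    for col in DE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"DE table missing column {col!r}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
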