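"""Readers, writers and normalization for the pipeline's external formats.

Expression matrices are delimited text with features in rows (first column =
feature identifier, header row = sample identifiers), values on log2 scale.
Gene sets use the MSigDB GMT dialect. Sample annotations and target-prediction
lists are TSV with mandated headers (see README).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mirmaster")

SUBTYPES = ("mesenchymal", "differentiated", "proliferative", "immunoreactive")

#: tokens accepted as missing values in expression files
MISSING_TOKENS = ("NA", "", "NaN", "nan")

#: features with more than this fraction of missing entries are dropped
MAX_MISSING_FRACTION = 0.2


class FormatError(ValueError):
    """Malformed input file (bad header, wrong field count, unparseable cell)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass
class ExpressionMatrix:
    """Features x samples log2-scale expression.

    ``data`` is a float DataFrame whose index holds unique feature ids and
    whose columns hold unique sample ids; ``feature_kind`` is ``"gene"`` or
    ``"mirna"``.
    """

    data: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "mirna"):
            raise ValidationError(f"feature_kind must be gene|mirna, got {self.feature_kind!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values after loading")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, ids) -> "ExpressionMatrix":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise ValidationError(f"features absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(ids)], self.feature_kind)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        missing = [i for i in ids if i not in self.data.columns]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data[list(ids)], self.feature_kind)


@dataclass
class GeneSetCollection:
    """Named gene sets; ``sets`` maps name -> (description, frozenset of ids)."""

    sets: dict[str, tuple[str, frozenset]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def members(self, name: str) -> frozenset:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass
class TargetPredictionTable:
    """Sequence-based regulator -> predicted-target lists (miRDB/TargetScan-like)."""

    source_name: str
    targets: dict[str, frozenset] = field(default_factory=dict)

    def predicted(self, regulator_id: str) -> frozenset:
        """Targets predicted for ``regulator_id``; empty (with a warning) if absent."""
        if regulator_id not in self.targets:
            logger.warning(
                "regulator %s absent from prediction source %s; contributing no targets",
                regulator_id,
                self.source_name,
            )
            return frozenset()
        return self.targets[regulator_id]


@dataclass
class AnalysisConfig:
    """Every tunable threshold of the discovery pipeline.

    Defaults are the published operating point: classifier DE filter
    (log2FC > 1, BH P < 0.05), per-gene AUC > 0.9 keeping 10 genes, posterior
    call at 0.5; regulator filter log2FC < -0.5 at BH P < 1e-4; target filter
    |log2FC| > 0.25 at BH P < 0.05; 1000 permutations.
    """

    de_lfc_classifier: float = 1.0
    de_fdr_classifier: float = 0.05
    auc_min: float = 0.9
    n_classifier_genes: int = 10
    posterior_threshold: float = 0.5
    regulator_lfc_max: float = -0.5
    regulator_fdr: float = 1e-4
    target_abs_lfc_min: float = 0.25
    target_fdr: float = 0.05
    n_permutations: int = 1000
    n_bootstraps: int = 100
    bootstrap_consensus: float = 0.95
    dpi_tolerance: float = 0.0
    mra_fdr: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr_classifier", "regulator_fdr", "target_fdr",
                     "posterior_threshold", "bootstrap_consensus", "mra_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        for name in ("n_classifier_genes", "n_permutations", "n_bootstraps"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _detect_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_expression_matrix(path, feature_kind: str = "gene") -> ExpressionMatrix:
    """Read a delimited features x samples matrix, auto-detecting TSV vs CSV.

    Missing tokens (``NA``, empty, ``NaN``) are accepted; features missing in
    more than 20% of samples are dropped with a warning, remaining gaps are
    imputed with the feature's observed mean.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty or headerless file")
    sep = _detect_delimiter(header)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature ids {dups}")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")

    values = df.apply(lambda col: col.str.strip())
    is_missing = values.isin(MISSING_TOKENS)
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {values.iat[r, c]!r} at feature "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    missing_frac = numeric.isna().mean(axis=1)
    dropped = numeric.index[missing_frac > MAX_MISSING_FRACTION]
    if len(dropped):
        logger.warning("dropping %d features with >%.0f%% missing values: %s",
                       len(dropped), 100 * MAX_MISSING_FRACTION, list(dropped[:10]))
        numeric = numeric.drop(index=dropped)
    if numeric.isna().to_numpy().any():
        row_means = numeric.mean(axis=1)
        numeric = numeric.apply(lambda col: col.fillna(row_means))
    return ExpressionMatrix(numeric.astype(float), feature_kind)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.data.sort_index()
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def znormalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-score across all samples (sd with n-1 denominator).

    Zero-variance features map to all-zero rows (logged). Idempotent up to
    floating-point error.
    """
    if m.n_samples < 2:
        raise ValidationError("z-normalization requires at least 2 samples")
    vals = m.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("%d zero-variance features set to all-zero rows during z-normalization",
                       int(flat.sum()))
    sd[flat] = 1.0
    out = (vals - mean) / sd
    out[flat[:, 0] if flat.ndim > 1 else flat] = 0.0
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                            m.feature_kind)


def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name TAB description TAB member..."""
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields, "
                                  f"got {len(fields)}")
            name, desc, *members = fields
            name = name.strip()
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(mem.strip() for mem in members if mem.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc, members = collection.sets[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


_SAMPLE_COLUMNS = ("subtype", "time", "event", "age", "stage", "grade")


def read_sample_table(path) -> pd.DataFrame:
    """Per-sample annotations: subtype, survival time/event, age/stage/grade.

    Requires a ``sample_id`` column; all other columns are optional. Subtype
    labels are case-folded to the canonical four-subtype vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing mandatory 'sample_id' column")
    df["sample_id"] = df["sample_id"].str.strip()
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    df = df.set_index("sample_id")
    if "subtype" in df.columns:
        folded = df["subtype"].astype(str).str.strip().str.lower()
        folded = folded.replace({"nan": np.nan, "": np.nan, "na": np.nan})
        unknown = folded.dropna()[~folded.dropna().isin(SUBTYPES)]
        if len(unknown):
            raise ValidationError(
                f"{path}: unknown subtype labels {sorted(unknown.unique())}; "
                f"allowed: {list(SUBTYPES)}"
            )
        df["subtype"] = folded
    if "time" in df.columns:
        df["time"] = pd.to_numeric(df["time"])
        if (df["time"].dropna() < 0).any():
            raise ValidationError(f"{path}: negative survival times")
    if "event" in df.columns:
        df["event"] = pd.to_numeric(df["event"])
        bad = df["event"].dropna()[~df["event"].dropna().isin((0, 1))]
        if len(bad):
            raise ValidationError(f"{path}: event flags must be 0/1")
        df["event"] = df["event"].astype("Int64")
    for col in ("age", "stage", "grade"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.sort_index().to_csv(path, sep="\t", index_label="sample_id")


def read_target_predictions(path, source_name: str) -> TargetPredictionTable:
    """Two-column TSV (regulator TAB target); duplicate pairs collapse silently."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (regulator, target)")
    reg_col, tgt_col = df.columns[:2]
    mapping: dict[str, set] = {}
    for reg, tgt in zip(df[reg_col].str.strip(), df[tgt_col].str.strip()):
        mapping.setdefault(reg, set()).add(tgt)
    return TargetPredictionTable(source_name, {k: frozenset(v) for k, v in mapping.items()})


def write_target_predictions(table: TargetPredictionTable, path) -> None:
    rows = [(reg, tgt) for reg in sorted(table.targets) for tgt in sorted(table.targets[reg])]
    pd.DataFrame(rows, columns=["regulator_id", "target_id"]).to_csv(path, sep="\t", index=False)


def write_results_table(df: pd.DataFrame, path, sort_by=None) -> None:
    """Write a results DataFrame as TSV with deterministic row/column order."""
    out = df.copy()
    if sort_by is not None:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
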