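"""Corpus data model and delimited-text I/O.

The engine consumes per-experiment ("contrast") differential-expression
tables, experiment metadata mapping each contrast to a signaling node and
biosample, BED-like ChIP-Seq peak tables with a TSS annotation, and gene
sets; it emits ranked consensome spreadsheets with a version-stamp header.

All tabular data live in pandas DataFrames with fixed column names;
lightweight dataclasses carry identity and validated structure around them.
Fold changes are stored in two synchronized representations: the linear
ratio ``fold_change`` and ``log2_fold_change``. The log2 column is the
canonical one for downstream arithmetic (its negation under fold-change
inversion is exact in floating point, which keeps direction-suppressed
statistics exactly symmetric).
"""

from __future__ import annotations

import datetime as _dt
import io as _io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ContractError",
    "VocabularyError",
    "TableDialect",
    "BedDialect",
    "LoadReport",
    "ExperimentTable",
    "GeneSet",
    "VersionStamp",
    "CistromeExperiment",
    "read_experiment_table",
    "read_metadata_table",
    "read_peak_table",
    "read_tss_table",
    "read_gene_set",
    "read_gmt",
    "write_gene_set",
    "write_consensome",
    "read_consensome",
]


class FormatError(ValueError):
    """A file does not have the structure the dialect promises."""


class ValidationError(ValueError):
    """Structurally parseable content violates a domain invariant."""


class ContractError(RuntimeError):
    """An operation was called outside its contract."""


class VocabularyError(ValueError):
    """A selector references a term absent from the corpus vocabulary."""


#: Canonical column order of an experiment table once loaded.
EXPERIMENT_COLUMNS = ["probeset_id", "gene_id", "fold_change", "log2_fold_change", "p_value"]

#: Required metadata columns (``bsm_id`` and ``path`` are optional extras).
METADATA_COLUMNS = [
    "experiment_id",
    "dataset_id",
    "node_symbols",
    "node_family",
    "node_class",
    "node_category",
    "species",
    "system",
    "organ",
    "perturbation_type",
]

#: Data columns of a ranked transcriptomic consensome.
CONSENSOME_COLUMNS = [
    "gene_id",
    "n_experiments",
    "n_discoveries",
    "discovery_rate",
    "cpv",
    "consensus_fc",
    "rank",
    "percentile",
]


@dataclass(frozen=True)
class TableDialect:
    """Column mapping and scale declaration for an experiment table.

    ``fold_change_scale`` declares whether the fold-change column holds a
    linear ratio (``"linear"``) or a log2 ratio (``"log2"``); internally
    everything is converted to the canonical pair (linear, log2).
    """

    sep: str = "\t"
    probeset_id: str = "probeset_id"
    gene_id: str = "gene_id"
    fold_change: str = "fold_change"
    p_value: str = "p_value"
    fold_change_scale: str = "linear"

    def __post_init__(self) -> None:
        if self.fold_change_scale not in ("linear", "log2"):
            raise ValueError(f"fold_change_scale must be 'linear' or 'log2', got {self.fold_change_scale!r}")


@dataclass(frozen=True)
class BedDialect:
    """BED-like peak-table dialect; 0-based half-open coordinates.

    ``score_column`` is the 0-based index of the MACS2 score column
    (default 3, i.e. BED4 chrom/start/end/score).
    """

    score_column: int = 3


@dataclass(frozen=True)
class LoadReport:
    """Accounting of rows seen and dropped while loading one table."""

    n_rows: int
    n_dropped_missing_gene: int


@dataclass
class ExperimentTable:
    """All probeset-level measurements of one contrast.

    ``data`` has columns ``probeset_id, gene_id, fold_change,
    log2_fold_change, p_value``; (probeset_id, gene_id) pairs are unique,
    fold changes strictly positive, p-values within [0, 1].
    """

    experiment_id: str
    data: pd.DataFrame
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("probeset_id", "gene_id", "fold_change", "p_value") if c not in df.columns]
        if missing:
            raise FormatError(f"experiment table {self.experiment_id!r} lacks columns {missing}")
        if len(df) == 0:
            raise ValidationError(f"experiment table {self.experiment_id!r} is empty")
        if "log2_fold_change" not in df.columns:
            with np.errstate(divide="ignore", invalid="ignore"):  # validated below
                df = df.assign(log2_fold_change=np.log2(df["fold_change"].to_numpy(dtype=float)))
        self.data = df.loc[:, EXPERIMENT_COLUMNS].reset_index(drop=True)
        _validate_measurements(self.data, self.experiment_id)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.data["gene_id"].unique()

    def invert(self) -> "ExperimentTable":
        """Return the table with every fold change replaced by its reciprocal.

        Performed by negating the log2 column (exact), then re-deriving the
        linear ratio, so direction-suppressed statistics are bit-identical
        between a table and its inversion.
        """
        df = self.data.copy()
        df["log2_fold_change"] = -df["log2_fold_change"]
        df["fold_change"] = np.exp2(df["log2_fold_change"].to_numpy())
        return ExperimentTable(self.experiment_id, df)


def _validate_measurements(df: pd.DataFrame, experiment_id: str) -> None:
    fc = df["fold_change"].to_numpy(dtype=float)
    p = df["p_value"].to_numpy(dtype=float)
    bad = ~(fc > 0) | ~np.isfinite(fc)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{experiment_id!r} row {i} (probeset {df['probeset_id'].iat[i]!r}): "
            f"fold change must be a positive finite ratio, got {fc[i]!r}"
        )
    bad = (p < 0) | (p > 1) | ~np.isfinite(p)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{experiment_id!r} row {i} (probeset {df['probeset_id'].iat[i]!r}): "
            f"p-value must lie in [0, 1], got {p[i]!r}"
        )
    dup = df.duplicated(subset=["probeset_id", "gene_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{experiment_id!r} row {i}: duplicate (probeset_id, gene_id) pair "
            f"({df['probeset_id'].iat[i]!r}, {df['gene_id'].iat[i]!r})"
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers (case-sensitive symbols)."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id) -> bool:
        return gene_id in self.members


@dataclass(frozen=True)
class VersionStamp:
    """Provenance header of a consensome: version, date and corpus counts."""

    version: str
    date: str
    n_datapoints: int
    n_experiments: int
    n_datasets: int

    @classmethod
    def now(cls, version: str, n_datapoints: int, n_experiments: int, n_datasets: int) -> "VersionStamp":
        return cls(version, _dt.date.today().isoformat(), n_datapoints, n_experiments, n_datasets)


@dataclass
class CistromeExperiment:
    """One ChIP-Seq experiment: called peaks plus node/biosample mapping."""

    experiment_id: str
    dataset_id: str
    ip_node: str
    node_family: str
    system: str
    organ: str
    species: str
    peaks: pd.DataFrame
    bsm_id: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "start", "end", "score") if c not in self.peaks.columns]
        if missing:
            raise FormatError(f"peak table of {self.experiment_id!r} lacks columns {missing}")


# ---------------------------------------------------------------------------
# readers


def read_experiment_table(path, dialect: TableDialect | None = None, experiment_id: str | None = None) -> ExperimentTable:
    """Read one contrast's probeset-level table.

    Log2 fold changes (per the dialect) are converted to linear ratios;
    rows with a missing gene identifier are dropped and counted in the
    table's :class:`LoadReport`.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep, float_precision="round_trip")
    mapping = {
        dialect.probeset_id: "probeset_id",
        dialect.gene_id: "gene_id",
        dialect.fold_change: "fold_change",
        dialect.p_value: "p_value",
    }
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}")
    df = df.rename(columns=mapping)
    n_rows = len(df)
    keep = df["gene_id"].notna() & (df["gene_id"].astype(str).str.strip() != "")
    df = df.loc[keep].copy()
    report = LoadReport(n_rows=n_rows, n_dropped_missing_gene=n_rows - len(df))
    df["gene_id"] = df["gene_id"].astype(str)
    df["probeset_id"] = df["probeset_id"].astype(str)
    fc = pd.to_numeric(df["fold_change"], errors="coerce").to_numpy(dtype=float)
    if dialect.fold_change_scale == "log2":
        df["log2_fold_change"] = fc
        df["fold_change"] = np.exp2(fc)
    else:
        df["fold_change"] = fc
        df["log2_fold_change"] = np.log2(fc)
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    exp_id = experiment_id if experiment_id is not None else path.stem
    return ExperimentTable(exp_id, df, load_report=report)


def read_metadata_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read the experiment-metadata table (one row per experiment).

    Multi-node experiments list several symbols/families separated by ';'.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata lacks column(s) {missing}")
    if df["experiment_id"].duplicated().any():
        dups = df.loc[df["experiment_id"].duplicated(), "experiment_id"].tolist()
        raise ValidationError(f"{path}: duplicate experiment_id(s) {dups}")
    return df


def read_peak_table(path, dialect: BedDialect | None = None) -> pd.DataFrame:
    """Read a BED-like peak table into columns chrom/start/end/score.

    Coordinates stay 0-based half-open as in BED. An empty file yields an
    empty frame with a warning rather than an error.
    """
    dialect = dialect or BedDialect()
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=r"\s+", engine="python", header=None, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty peak file", stacklevel=2)
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64), "score": pd.Series(dtype=float)})
    if raw.shape[1] <= dialect.score_column:
        raise FormatError(f"{path}: expected at least {dialect.score_column + 1} columns, found {raw.shape[1]}")
    df = pd.DataFrame(
        {
            "chrom": raw.iloc[:, 0].astype(str),
            "start": raw.iloc[:, 1].astype(np.int64),
            "end": raw.iloc[:, 2].astype(np.int64),
            "score": raw.iloc[:, dialect.score_column].astype(float),
        }
    )
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"{path} row {i}: start >= end ({df['start'].iat[i]} >= {df['end'].iat[i]})")
    if (df["score"] < 0).any():
        i = int(np.flatnonzero((df["score"] < 0).to_numpy())[0])
        raise ValidationError(f"{path} row {i}: negative score {df['score'].iat[i]}")
    return df


def read_tss_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read the TSS annotation (gene_id, chrom, tss, strand); tss is 1-based."""
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str, "chrom": str})
    missing = [c for c in ("gene_id", "chrom", "tss", "strand") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: TSS table lacks column(s) {missing}")
    df["tss"] = df["tss"].astype(np.int64)
    if (df["tss"] < 1).any():
        raise ValidationError(f"{path}: TSS coordinates are 1-based and must be >= 1")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{path}: strand must be '+' or '-'")
    if df.duplicated(subset=["gene_id", "chrom", "tss"]).any():
        raise ValidationError(f"{path}: duplicate (gene_id, chrom, tss) records")
    return df.reset_index(drop=True)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene set; blank lines and '#' comments skipped."""
    path = Path(path)
    members = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            members.append(line)
    return GeneSet(name or path.stem, frozenset(members))


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets in GMT format (name <tab> description <tab> genes...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: GMT lines need >= 3 tab-separated fields, got {len(fields)}")
        sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")


# ---------------------------------------------------------------------------
# consensome spreadsheet

_HEADER_PREFIX = "# "


def write_consensome(rows: pd.DataFrame, stamp: VersionStamp, path, selector=None, sep: str = "\t") -> None:
    """Write a ranked consensome with its version-stamp header block.

    The header carries the selector (node family / system / organ /
    species), version, date, and the corpus counts (data points,
    experiments, datasets); numeric fields round-trip to 12 significant
    digits through :func:`read_consensome`.
    """
    rows = pd.DataFrame(rows)
    if len(rows) and "rank" not in rows.columns:
        raise ContractError("consensome rows must be ranked before writing (missing 'rank' column)")
    if len(rows) == 0:
        warnings.warn("writing header-only consensome: no rows", stacklevel=2)
    header = {
        "node_family": getattr(selector, "node_family", "All") if selector is not None else "All",
        "system": getattr(selector, "system", "All") if selector is not None else "All",
        "organ": getattr(selector, "organ", "All") if selector is not None else "All",
        "species": getattr(selector, "species", "All") if selector is not None else "All",
        "version": stamp.version,
        "date": stamp.date,
        "n_datapoints": stamp.n_datapoints,
        "n_experiments": stamp.n_experiments,
        "n_datasets": stamp.n_datasets,
    }
    buf = _io.StringIO()
    for key, value in header.items():
        buf.write(f"{_HEADER_PREFIX}{key}: {value}\n")
    cols = [c for c in CONSENSOME_COLUMNS if c in rows.columns] + [
        c for c in rows.columns if c not in CONSENSOME_COLUMNS
    ]
    out = rows.loc[:, cols] if len(rows) else pd.DataFrame(columns=cols)
    out.to_csv(buf, sep=sep, index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue())


def read_consensome(path, sep: str = "\t") -> tuple[pd.DataFrame, dict, VersionStamp]:
    """Read a consensome file back into (rows, selector dict, stamp)."""
    path = Path(path)
    header: dict[str, str] = {}
    body_lines = []
    for line in path.read_text().splitlines():
        if line.startswith(_HEADER_PREFIX) and not body_lines:
            key, _, value = line[len(_HEADER_PREFIX):].partition(": ")
            header[key] = value
        else:
            body_lines.append(line)
    required = {"version", "date", "n_datapoints", "n_experiments", "n_datasets"}
    if not required.issubset(header):
        raise FormatError(f"{path}: consensome header lacks {sorted(required - set(header))}")
    stamp = VersionStamp(
        version=header["version"],
        date=header["date"],
        n_datapoints=int(header["n_datapoints"]),
        n_experiments=int(header["n_experiments"]),
        n_datasets=int(header["n_datasets"]),
    )
    selector = {k: header.get(k, "All") for k in ("node_family", "system", "organ", "species")}
    body = "\n".join(body_lines)
    if body.strip():
        rows = pd.read_csv(_io.StringIO(body), sep=sep, dtype={"gene_id": str}, float_precision="round_trip")
    else:
        rows = pd.DataFrame(columns=CONSENSOME_COLUMNS)
    return rows, selector, stamp
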