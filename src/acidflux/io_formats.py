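"""Typed readers and writers for every table the pipeline touches.

All downstream stages operate on the validated containers defined here:
gene-by-sample count matrices, sample design tables, regulatory edge
lists, growth curves (OD600 with optional pH and CFU traces), and
per-contrast differential-expression tables.  Files are plain UTF-8
TSV/CSV with "." as the decimal separator; the delimiter is inferred
from the file extension (.csv -> comma, anything else -> tab) unless
given explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "NetworkEdgeList",
    "GrowthCurve",
    "DETable",
    "FormatError",
    "read_count_matrix",
    "read_design",
    "read_network",
    "read_growth_csv",
    "read_de_table",
    "write_count_matrix",
    "write_design",
    "write_network",
    "write_growth_csv",
    "write_de_table",
    "write_reporter_table",
    "write_summary_json",
]

REGIMES = ("acute", "sustained")
CONDITIONS = ("stress", "control")
EFFECTS = ("activation", "repression", "dual")

#: case-insensitive synonyms accepted in network "effect" columns
EFFECT_SYNONYMS = {
    "activation": "activation",
    "repression": "repression",
    "dual": "dual",
    "+": "activation",
    "-": "repression",
    "−": "repression",  # unicode minus
    "±": "dual",  # plus-minus sign
    "act": "activation",
    "rep": "repression",
}

DE_TABLE_COLUMNS = ("gene_id", "log2fc", "p", "p_adj", "mean_cpm")


class FormatError(ValueError):
    """Raised when an input file violates a format or type invariant."""


def _delimiter(path: str | os.PathLike, dialect: str | None = None) -> str:
    if dialect is not None:
        if dialect in ("\t", "tab", "tsv"):
            return "\t"
        if dialect in (",", "comma", "csv"):
            return ","
        raise ValueError(f"unknown dialect {dialect!r}")
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative integer gene x sample expression counts."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # (n_genes, n_samples) int64

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            g, s = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(self.gene_ids, tuple(sample_ids), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample experimental annotation.

    Each row maps a sample id onto (regime, condition, timepoint_h,
    replicate).  Regimes are 'acute' (pH 4.0 shock vs pH 7.0 at 1, 4 h)
    or 'sustained' (pH 5.5 vs pH 7.0 at 1, 8, 18 h) in the study this
    pipeline models, but any regime/timepoint layout is accepted.
    """

    table: pd.DataFrame  # index: sample_id; columns regime, condition, timepoint_h, replicate

    REQUIRED = ("regime", "condition", "timepoint_h", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in design: {dups}")
        bad = set(t["regime"]) - set(REGIMES)
        if bad:
            raise FormatError(f"unknown regimes {sorted(bad)}; expected {REGIMES}")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        if (t["timepoint_h"] <= 0).any():
            raise FormatError("timepoint_h must be positive")
        if (t["replicate"] < 1).any():
            raise FormatError("replicate must be a positive integer")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def samples_for(
        self, regime: str, condition: str, timepoint_h: float
    ) -> tuple[str, ...]:
        t = self.table
        mask = (
            (t["regime"] == regime)
            & (t["condition"] == condition)
            & (t["timepoint_h"] == timepoint_h)
        )
        return tuple(t.index[mask])

    def timepoints(self, regime: str) -> tuple[float, ...]:
        t = self.table
        return tuple(sorted(set(t.loc[t["regime"] == regime, "timepoint_h"])))

    def validate_against(self, counts: CountMatrix) -> None:
        missing = set(counts.sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples without design rows: {sorted(missing)}")


@dataclass(frozen=True)
class NetworkEdgeList:
    """Raw TF -> target edges with effect labels, in input order."""

    edges: tuple[tuple[str, str, str], ...]  # (tf_id, target_id, effect)

    def __post_init__(self) -> None:
        for i, (tf, tgt, eff) in enumerate(self.edges):
            if not tf or not tgt:
                raise FormatError(f"empty id in edge row {i}: {(tf, tgt, eff)}")
            if eff not in EFFECTS:
                raise FormatError(
                    f"edge row {i} ({tf} -> {tgt}): unknown effect {eff!r}; "
                    f"expected one of {EFFECTS}"
                )

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


@dataclass(frozen=True)
class GrowthCurve:
    """Timed OD600 series with optional pH and CFU/mL traces."""

    time_h: np.ndarray
    od: np.ndarray
    ph: np.ndarray | None = None
    cfu_per_ml: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or od.shape != t.shape:
            raise FormatError("time_h and od must be 1-D arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise FormatError("time_h must be strictly increasing")
        if np.any(od <= 0):
            raise FormatError("od values must be positive")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "od", od)
        for name in ("ph", "cfu_per_ml"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != t.shape:
                    raise FormatError(f"{name} must match time_h in length")
                object.__setattr__(self, name, v)
        if self.ph is not None and (np.any(self.ph < 0) or np.any(self.ph > 14)):
            raise FormatError("ph values must lie in [0, 14]")
        if self.cfu_per_ml is not None and np.any(self.cfu_per_ml <= 0):
            raise FormatError("cfu_per_ml values must be positive")

    def __len__(self) -> int:
        return len(self.time_h)


@dataclass(frozen=True)
class DETable:
    """Per-gene contrast statistics: log2FC, p, BH-adjusted p, mean CPM."""

    table: pd.DataFrame  # columns gene_id, log2fc, p, p_adj, mean_cpm

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DE_TABLE_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"DE table missing columns: {missing}")
        if t["gene_id"].duplicated().any():
            raise FormatError("duplicate gene ids in DE table")
        for col in ("p", "p_adj"):
            v = t[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise FormatError(f"{col} outside [0, 1]")
        if np.any(t["p_adj"].to_numpy() + 1e-12 < t["p"].to_numpy()):
            raise FormatError("p_adj must be >= p")
        if (t["mean_cpm"] < 0).any():
            raise FormatError("mean_cpm must be nonnegative")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers


def read_count_matrix(path: str | os.PathLike, dialect: str | None = None) -> CountMatrix:
    """Read a genes x samples count table (first column = gene ids)."""
    sep = _delimiter(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        numeric = pd.to_numeric(pd.Series(raw), errors="coerce")
        if numeric.isna().any():
            i = int(np.flatnonzero(numeric.isna())[0])
            raise FormatError(
                f"{path}: non-numeric entry {raw[i]!r} at gene "
                f"{df.index[i]!r}, sample {col!r}"
            )
        arr = numeric.to_numpy(dtype=float)
        if np.any(arr != np.floor(arr)):
            i = int(np.flatnonzero(arr != np.floor(arr))[0])
            raise FormatError(
                f"{path}: non-integer count {arr[i]} at gene "
                f"{df.index[i]!r}, sample {col!r}"
            )
        if np.any(arr < 0):
            i = int(np.flatnonzero(arr < 0)[0])
            raise FormatError(
                f"{path}: negative count at gene {df.index[i]!r}, sample {col!r}"
            )
        values[:, j] = arr.astype(np.int64)
    return CountMatrix(tuple(df.index), tuple(df.columns), values)


def read_design(path: str | os.PathLike, dialect: str | None = None) -> SampleDesign:
    """Read a sample design table (sample_id, regime, condition, timepoint_h, replicate)."""
    sep = _delimiter(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    df["timepoint_h"] = pd.to_numeric(df["timepoint_h"])
    df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")
    return SampleDesign(df)


def read_network(
    path: str | os.PathLike,
    dialect: str | None = None,
    effect_vocabulary: Mapping[str, str] | None = None,
) -> NetworkEdgeList:
    """Read a TF/target/effect edge list, mapping effect synonyms.

    The effect vocabulary defaults to {activation, repression, dual}
    plus the case-insensitive synonyms "+", "-", "±", "act", "rep".
    """
    sep = _delimiter(path, dialect)
    vocab = dict(EFFECT_SYNONYMS if effect_vocabulary is None else effect_vocabulary)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in ("tf", "target", "effect") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    edges = []
    for i, row in enumerate(df.itertuples(index=False)):
        tf, target, effect = str(row.tf), str(row.target), str(row.effect)
        key = effect.strip().lower()
        if key not in vocab:
            raise FormatError(
                f"{path}: row {i} ({tf} -> {target}): unknown effect "
                f"label {effect!r}"
            )
        edges.append((tf, target, vocab[key]))
    return NetworkEdgeList(tuple(edges))


def read_growth_csv(path: str | os.PathLike, dialect: str | None = None) -> GrowthCurve:
    """Read a growth curve CSV (time_h, od600[, ph][, cfu_per_ml])."""
    sep = _delimiter(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in ("time_h", "od600") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return GrowthCurve(
        time_h=df["time_h"].to_numpy(dtype=float),
        od=df["od600"].to_numpy(dtype=float),
        ph=df["ph"].to_numpy(dtype=float) if "ph" in df.columns else None,
        cfu_per_ml=(
            df["cfu_per_ml"].to_numpy(dtype=float)
            if "cfu_per_ml" in df.columns
            else None
        ),
    )


def read_de_table(path: str | os.PathLike, dialect: str | None = None) -> DETable:
    """Read an (internally or externally produced) DE table TSV."""
    sep = _delimiter(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"gene_id": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    return DETable(df)


# ---------------------------------------------------------------------------
# writers — value columns use repr-precision floats so write∘read round-trips
# to at least 12 significant digits

_FLOAT_FMT = "%.17g"


def write_count_matrix(cm: CountMatrix, path: str | os.PathLike) -> None:
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=_delimiter(path))


def write_design(design: SampleDesign, path: str | os.PathLike) -> None:
    df = design.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_delimiter(path))


def write_network(net: NetworkEdgeList, path: str | os.PathLike) -> None:
    df = pd.DataFrame(list(net.edges), columns=["tf", "target", "effect"])
    df.to_csv(path, sep=_delimiter(path), index=False)


def write_growth_csv(curve: GrowthCurve, path: str | os.PathLike) -> None:
    data: dict[str, np.ndarray] = {"time_h": curve.time_h, "od600": curve.od}
    if curve.ph is not None:
        data["ph"] = curve.ph
    if curve.cfu_per_ml is not None:
        data["cfu_per_ml"] = curve.cfu_per_ml
    pd.DataFrame(data).to_csv(
        path, sep=_delimiter(path), index=False, float_format=_FLOAT_FMT
    )


def write_de_table(table: DETable, path: str | os.PathLike) -> None:
    cols = list(DE_TABLE_COLUMNS) + [
        c for c in table.table.columns if c not in DE_TABLE_COLUMNS
    ]
    table.table[cols].to_csv(
        path, sep=_delimiter(path), index=False, float_format=_FLOAT_FMT
    )


def write_reporter_table(results: Iterable, path: str | os.PathLike) -> None:
    """Write reporter-TF results (list of ReporterResult dataclasses) as TSV."""
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep=_delimiter(path), index=False, float_format=_FLOAT_FMT)


def write_summary_json(summary: Mapping, path: str | os.PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=default)
        fh.write("\n")
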