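"""Reading and writing expression matrices, sample metadata and gene sets.

Expression matrices are tab-separated text, genes in rows (first column
``gene_id``), samples in columns, values on a log2 scale. Gene sets use the
standard GMT format. Sample metadata is a TSV keyed by ``sample_id`` with the
columns of :class:`SampleAnnotation`; unrecognised numeric columns are kept as
auxiliary per-sample quantities (e.g. PD-L1 expression, mutation burden).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "LogScaleReport",
    "EGFR_STATUSES",
    "KRAS_STATUSES",
    "load_expression",
    "write_expression",
    "collapse_probes",
    "load_gmt",
    "write_gmt",
    "load_metadata",
    "check_log_scale",
]

EGFR_STATUSES = frozenset(
    {"wild_type", "hotspot_mutant", "vus", "other_mutant", "unknown"}
)
KRAS_STATUSES = frozenset({"wild_type", "mutant", "unknown"})

#: values above this look like linear-scale intensities, not log2 values
LINEAR_SCALE_MAX = 50.0


class ParseError(ValueError):
    """Malformed input file; the message names the offending line/cell."""


@dataclass
class ExpressionMatrix:
    """A log2-scale gene-by-sample abundance table.

    Parameters
    ----------
    data
        DataFrame with unique gene ids as index and unique sample ids as
        columns; all values finite floats. At least 2 genes and 2 samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=2 samples, got {df.shape}"
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite or non-numeric values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the up/down EGFR signatures) as in a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class LogScaleReport:
    """Heuristic diagnostic for whether a matrix is plausibly log-scale."""

    max_value: float
    plausible: bool
    message: str


def _coerce_frame(obj: "ExpressionMatrix | pd.DataFrame") -> pd.DataFrame:
    """Accept either an ExpressionMatrix or a bare genes x samples frame."""
    if isinstance(obj, ExpressionMatrix):
        return obj.data
    if isinstance(obj, pd.DataFrame):
        return obj
    raise TypeError(f"expected ExpressionMatrix or DataFrame, got {type(obj)!r}")


def collapse_probes(df: pd.DataFrame, how: str = "max_mean") -> pd.DataFrame:
    """Collapse probe-level rows sharing a gene id to one row per gene.

    ``max_mean`` keeps, among rows with the same id, the row whose mean across
    samples is highest — a deterministic rule, idempotent by construction.
    """
    if how == "none":
        return df
    if how != "max_mean":
        raise ValueError(f"unknown collapse rule {how!r}")
    if not df.index.has_duplicates:
        return df
    means = df.mean(axis=1).to_numpy()
    # stable sort: among equal means the first occurrence wins
    order = np.argsort(-means, kind="stable")
    picked = df.iloc[order]
    picked = picked[~picked.index.duplicated(keep="first")]
    # restore first-appearance gene order
    first_seen: dict[str, int] = {}
    for i, g in enumerate(df.index):
        first_seen.setdefault(g, i)
    return picked.loc[sorted(picked.index, key=first_seen.__getitem__)]


def load_expression(
    path: str | Path,
    collapse: str = "max_mean",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load a TSV expression matrix (first column gene/probe id, header row
    of sample ids). Non-numeric cells and malformed headers raise
    :class:`ParseError` naming the offending position."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise ParseError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: header row defines no sample columns")
    if transpose:
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    numeric = numeric.astype(float)
    if numeric.shape[0] == 0:
        raise ParseError(f"{path}: zero usable rows")
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "gene_id"
    collapsed = collapse_probes(numeric, how=collapse)
    return ExpressionMatrix(collapsed)


def write_expression(matrix: "ExpressionMatrix | pd.DataFrame", path: str | Path) -> None:
    df = _coerce_frame(matrix)
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description,
    genes. Duplicate genes within one line are dropped with a warning."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} removed",
                    stacklevel=2,
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


_ANNOTATION_COLUMNS = {
    "egfr_status": str,
    "kras_status": str,
    "rfs_time": float,
    "rfs_event": bool,
    "os_time": float,
    "os_event": bool,
    "shrinkage_rate": float,
    "ic50": float,
}


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Load a sample metadata TSV keyed by ``sample_id``.

    Known columns are validated (status enums, paired time/event flags);
    unknown columns are preserved untouched as auxiliary quantities.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if "egfr_status" in df.columns:
        bad = set(df["egfr_status"].dropna()) - EGFR_STATUSES
        if bad:
            raise ParseError(f"{path}: invalid egfr_status values {sorted(bad)}")
    if "kras_status" in df.columns:
        bad = set(df["kras_status"].dropna()) - KRAS_STATUSES
        if bad:
            raise ParseError(f"{path}: invalid kras_status values {sorted(bad)}")
    for time_col, event_col in (("rfs_time", "rfs_event"), ("os_time", "os_event")):
        if time_col in df.columns:
            if event_col not in df.columns:
                raise ParseError(f"{path}: {time_col} present without {event_col}")
            has_time = df[time_col].notna()
            if df.loc[has_time, event_col].isna().any():
                missing = df.index[has_time & df[event_col].isna()][0]
                raise ParseError(
                    f"{path}: sample {missing!r} has {time_col} but no {event_col}"
                )
            if (df.loc[has_time, time_col].astype(float) < 0).any():
                raise ParseError(f"{path}: negative {time_col} values")
    return df


def check_log_scale(matrix: "ExpressionMatrix | pd.DataFrame") -> LogScaleReport:
    """Flag matrices that look linear-scale (max value > 50). Report only;
    the data is never mutated."""
    df = _coerce_frame(matrix)
    max_value = float(df.to_numpy().max()) if df.size else float("nan")
    if max_value > LINEAR_SCALE_MAX:
        return LogScaleReport(
            max_value=max_value,
            plausible=False,
            message=(
                f"values look linear-scale (max {max_value:g} > {LINEAR_SCALE_MAX:g}); "
                "log2-transform before enrichment scoring"
            ),
        )
    return LogScaleReport(max_value=max_value, plausible=True, message="log-scale: plausible")
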