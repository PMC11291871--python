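"""Tabular domain types and TSV input/output.

Everything downstream of read mapping enters the pipeline as plain TSV:
MAG (or ASV) abundance matrices, sample metadata, gene read-count tables
with gene lengths, and gene-by-MAG presence/absence matrices.  This module
validates those files into the in-memory containers the rest of the
package operates on, and writes every result type back out with a stable
column order.

Conventions
-----------
* Tables are tab-separated, first column = row identifiers, header row =
  sample identifiers.  A coverM-style header dialect (sample names suffixed
  with a metric label such as ``"S1 RPKM"``) is auto-detected on read and
  stripped; it is never written.
* Missing cells are not allowed.  Absence must be encoded as ``0`` upstream:
  movement-flux averages need a defined value for every taxon/sample cell.
* Row/column order is preserved from file; pairwise outputs are sorted
  lexicographically so that reruns are byte-identical.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("magflux")

MEDIA = ("seawater", "sediment")
ZONES = ("slope", "bottom")
GROUPS = tuple(f"{z}_{m}" for z in ZONES for m in MEDIA)

#: Units an abundance table may declare.
UNITS = ("RPKM", "percent", "count")

#: coverM column-metric suffixes recognised (and stripped) on read,
#: longest first so that e.g. "Trimmed Mean" wins over "Mean".
COVERM_METRICS = (
    "Relative Abundance (%)",
    "Trimmed Mean",
    "Covered Fraction",
    "Covered Bases",
    "Reads per base",
    "Read Count",
    "Variance",
    "Length",
    "Mean",
    "RPKM",
    "TPM",
)

MAX_DEPTH_M = 11_100.0


def configure_logging(verbose: bool = False) -> None:
    """Send structured log lines to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


class TableError(ValueError):
    """Raised when an input table violates a documented invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbundanceTable:
    """Taxon-by-sample matrix of non-negative abundances with a declared unit.

    ``values`` has taxa as the index and samples as columns.  ``unit`` is one
    of :data:`UNITS`; RPKM is the unit used for movement-flux work, percent
    relative abundance for composition work.
    """

    values: pd.DataFrame
    unit: str = "RPKM"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise TableError(f"unknown abundance unit {self.unit!r}; expected one of {UNITS}")
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate taxon ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableError("abundance matrix contains non-numeric values")
        if np.isnan(arr).any():
            t, s = np.argwhere(np.isnan(arr))[0]
            raise TableError(f"missing value at taxon {df.index[t]!r}, sample {df.columns[s]!r}")
        if (arr < 0).any():
            t, s = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative abundance {arr[t, s]} at taxon {df.index[t]!r}, "
                f"sample {df.columns[s]!r}"
            )
        if self.unit == "percent":
            sums = arr.sum(axis=0)
            bad = np.nonzero(sums > 100 + 1e-6)[0]
            if bad.size:
                raise TableError(
                    f"percent column {df.columns[bad[0]]!r} sums to {sums[bad[0]]:.6f} > 100"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def threshold(self, detection_threshold: float) -> "AbundanceTable":
        """Zero every abundance strictly below ``detection_threshold``."""
        if detection_threshold <= 0:
            return self
        vals = self.values.where(self.values >= detection_threshold, 0.0)
        return replace(self, values=vals)


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sample: medium, zone and optional depth.

    ``group`` is the deterministic ``{zone}_{medium}`` habitat label, one of
    the four study groups (slope/bottom x seawater/sediment).
    """

    sample_id: str
    medium: str
    zone: str
    depth_m: float | None = None

    def __post_init__(self) -> None:
        if self.medium not in MEDIA:
            raise TableError(f"sample {self.sample_id!r}: unknown medium {self.medium!r}")
        if self.zone not in ZONES:
            raise TableError(f"sample {self.sample_id!r}: unknown zone {self.zone!r}")
        if self.depth_m is not None and not (0 <= self.depth_m <= MAX_DEPTH_M):
            raise TableError(
                f"sample {self.sample_id!r}: depth {self.depth_m} m outside [0, {MAX_DEPTH_M}]"
            )

    @property
    def group(self) -> str:
        return f"{self.zone}_{self.medium}"


@dataclass(frozen=True)
class GeneCountTable:
    """Gene read counts per sample plus per-gene lengths in bp."""

    counts: pd.DataFrame
    lengths_bp: pd.Series

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            raise TableError(f"duplicate gene ids: {df.index[df.index.duplicated()].tolist()}")
        if df.columns.duplicated().any():
            raise TableError("duplicate sample ids in gene count table")
        if not df.index.equals(self.lengths_bp.index):
            raise TableError("gene length index does not match count table index")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or np.isnan(arr).any():
            raise TableError("gene counts must be numeric with no missing cells")
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise TableError("gene counts must be non-negative integers")
        lengths = self.lengths_bp.to_numpy()
        if (lengths <= 0).any() or not np.allclose(lengths, np.round(lengths)):
            raise TableError("gene lengths must be positive integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class RunConfig:
    """Run parameters shared across pipeline stages.

    ``n_perm`` is the permutation count of the null model (default 9999),
    ``level`` the one-sided significance level of the classification
    (default 0.95), ``seed`` the mandatory random seed, and
    ``detection_threshold`` the minimum abundance treated as detection.
    """

    seed: int
    n_perm: int = 9999
    level: float = 0.95
    detection_threshold: float = 0.0
    paths: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise TableError(f"n_perm must be >= 1, got {self.n_perm}")
        if not (0.5 < self.level < 1.0):
            raise TableError(f"level must lie in (0.5, 1), got {self.level}")
        if self.detection_threshold < 0:
            raise TableError("detection_threshold must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a plain ``key: value`` config file (a YAML mapping)."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise TableError(f"config {path} is not a key: value mapping")
        known = {"seed", "n_perm", "level", "detection_threshold", "paths"}
        unknown = set(raw) - known
        if unknown:
            raise TableError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise TableError("config must set a seed")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "n_perm": self.n_perm,
            "level": self.level,
            "detection_threshold": self.detection_threshold,
        }
        if self.paths:
            data["paths"] = dict(self.paths)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv_strict(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = [str(c) for c in df.columns]
    return df


def _to_float(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Convert a string frame to float, naming the first offending cell."""
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise TableError(
                f"non-numeric {what} value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise TableError(f"missing {what} value at row {row!r}, column {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def strip_coverm_suffix(columns: Sequence[str]) -> list[str]:
    """Strip a shared coverM metric suffix (e.g. ``" RPKM"``) from headers.

    The dialect is detected only when *every* sample column carries the same
    known metric suffix; plain headers pass through untouched.
    """
    for metric in COVERM_METRICS:
        suffix = " " + metric
        if all(c.endswith(suffix) and len(c) > len(suffix) for c in columns):
            stripped = [c[: -len(suffix)].rstrip() for c in columns]
            logger.debug("stripped coverM suffix %r from %d columns", metric, len(columns))
            return stripped
    return list(columns)


def read_abundance_table(path: str | Path, unit: str = "RPKM") -> AbundanceTable:
    """Read a taxon-by-sample abundance TSV, accepting the coverM dialect."""
    df = _read_tsv_strict(path)
    df.columns = strip_coverm_suffix(list(df.columns))
    values = _to_float(df, "abundance")
    table = AbundanceTable(values=values, unit=unit)
    logger.info(
        "read abundance table %s: %d taxa x %d samples (%s)",
        path, len(table.taxon_ids), len(table.sample_ids), unit,
    )
    return table


def read_sample_metadata(path: str | Path) -> list[SampleInfo]:
    """Read sample metadata (columns: sample_id, medium, zone[, depth_m])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "medium", "zone"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"metadata {path} lacks columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableError(f"duplicate sample ids in metadata: {dups}")
    samples = []
    for _, row in df.iterrows():
        depth = row.get("depth_m")
        depth_m = float(depth) if depth not in (None, "") and pd.notna(depth) else None
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                medium=str(row["medium"]),
                zone=str(row["zone"]),
                depth_m=depth_m,
            )
        )
    logger.info("read metadata %s: %d samples", path, len(samples))
    return samples


def read_gene_counts(path: str | Path, length_column: str = "length") -> GeneCountTable:
    """Read a gene-by-sample count TSV containing a gene-length column."""
    df = _read_tsv_strict(path)
    if length_column not in df.columns:
        raise TableError(f"gene table {path} lacks length column {length_column!r}")
    lengths = pd.to_numeric(df[length_column], errors="raise").astype(np.int64)
    counts = _to_float(df.drop(columns=[length_column]), "count")
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise TableError(
            f"gene counts must be integers: {arr[g, s]} at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    return GeneCountTable(counts=counts.astype(np.int64), lengths_bp=lengths)


def read_presence_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-MAG presence/absence (0/1) TSV."""
    df = _to_float(_read_tsv_strict(path), "presence")
    arr = df.to_numpy()
    if not np.isin(arr, (0.0, 1.0)).all():
        t, s = np.argwhere(~np.isin(arr, (0.0, 1.0)))[0]
        raise TableError(
            f"non-binary presence value {arr[t, s]} at row {df.index[t]!r}, "
            f"column {df.columns[s]!r}"
        )
    return df.astype(np.int8)


def read_origin_map(path: str | Path) -> dict[str, str]:
    """Read an explicit taxon -> origin-sample map (two-column TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableError(f"origin map {path} needs two columns (taxon, sample)")
    taxa, origins = df.iloc[:, 0], df.iloc[:, 1]
    if taxa.duplicated().any():
        raise TableError(f"duplicate taxa in origin map: {taxa[taxa.duplicated()].tolist()}")
    return dict(zip(taxa.astype(str), origins.astype(str)))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="taxon_id")


def write_metadata(samples: Iterable[SampleInfo], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "medium": s.medium,
            "zone": s.zone,
            "group": s.group,
            "depth_m": "" if s.depth_m is None else s.depth_m,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "medium", "zone", "group", "depth_m"]).to_csv(
        path, sep="\t", index=False
    )


def write_origin_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"taxon_id": list(mapping), "origin_sample": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def write_square_matrix(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_records(records: Sequence[Mapping], columns: Sequence[str], path: str | Path) -> None:
    """Write result records as a TSV with a fixed column order.

    An empty record list still yields a header-only file.
    """
    pd.DataFrame(list(records), columns=list(columns)).to_csv(path, sep="\t", index=False)


def write_edge_list(graph, path: str | Path) -> None:
    """Write a network as a 3-column edge list (node1, node2, weight)."""
    rows = [
        {"node1": str(u), "node2": str(v), "weight": d.get("weight", 1.0)}
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    write_records(rows, ["node1", "node2", "weight"], path)
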