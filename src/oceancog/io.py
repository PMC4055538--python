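"""Domain types and tab-separated I/O for COG profiling tables.

The package exchanges four kinds of flat tables (documented in FORMAT.md):

* a COG count matrix (rows = COG ids, columns = dataset ids, integer counts),
* per-dataset metadata (site, depth, PAR, dissolved oxygen),
* per-read COG/taxonomy assignments (one row per read),
* generic result tables (statistics, p-values, directions).

All files are plain TSV with a header row, UTF-8, ``.`` decimal separator and
no quoting, so that integer counts round-trip bit-exactly. Missing
(COG, dataset) cells are zero, never missing: shotgun counting semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "DatasetMetadata",
    "COGCountMatrix",
    "READ_TABLE_COLUMNS",
    "SUPERKINGDOMS",
    "validate_read_table",
    "read_cog_counts",
    "write_cog_counts",
    "read_metadata",
    "write_metadata",
    "read_read_assignments",
    "write_read_assignments",
    "read_result",
    "write_result",
]

READ_TABLE_COLUMNS = ("read_id", "dataset_id", "cog_id", "superkingdom", "phylum")
SUPERKINGDOMS = frozenset({"Bacteria", "Archaea", "Eukarya", "unidentified"})

ZoneLabel = Literal["photic", "aphotic", "unset"]


@dataclass(frozen=True)
class DatasetMetadata:
    """Physical context of one metagenomic dataset.

    Parameters
    ----------
    dataset_id, site:
        Identifiers; ``dataset_id`` is unique across a study.
    depth_m:
        Sampling depth in meters (>= 0).
    do_umol_kg:
        Dissolved oxygen, µmol·kg⁻¹ (>= 0).
    par_surface, par_at_depth:
        Photosynthetically active radiation at the surface and at the
        sampling depth (µmol photons m⁻² s⁻¹). Either ``par_at_depth`` or a
        diffuse attenuation coefficient ``attenuation_k`` (m⁻¹) is needed to
        call the photic/aphotic zone from the 1%-of-surface-PAR rule.
    zone_label:
        Photic/aphotic call, ``"unset"`` until assigned.
    """

    dataset_id: str
    site: str
    depth_m: float
    do_umol_kg: float
    par_surface: float | None = None
    par_at_depth: float | None = None
    attenuation_k: float | None = None
    zone_label: ZoneLabel = "unset"

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValidationError("dataset_id must be non-empty")
        if not np.isfinite(self.depth_m) or self.depth_m < 0:
            raise ValidationError(
                f"depth_m must be a finite non-negative number, got {self.depth_m!r}"
            )
        if not np.isfinite(self.do_umol_kg) or self.do_umol_kg < 0:
            raise ValidationError(
                f"do_umol_kg must be finite and non-negative, got {self.do_umol_kg!r}"
            )
        for name in ("par_surface", "par_at_depth"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be finite and non-negative")
        if self.attenuation_k is not None and not self.attenuation_k > 0:
            raise ValidationError("attenuation_k must be positive")
        if self.zone_label not in ("photic", "aphotic", "unset"):
            raise ValidationError(f"unknown zone_label {self.zone_label!r}")

    def with_zone(self, zone: ZoneLabel) -> "DatasetMetadata":
        return replace(self, zone_label=zone)


@dataclass
class COGCountMatrix:
    """Integer read counts per COG per dataset plus per-dataset library sizes.

    ``counts`` is a pandas DataFrame indexed by COG id with one column per
    dataset; ``library_size`` maps each dataset to its total number of
    assigned reads. Column sums may be below the library size (reads assigned
    to no COG), never above it.
    """

    counts: pd.DataFrame
    library_size: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate COG ids: {dupes}")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate dataset ids in count matrix")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValidationError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
            self.counts = counts
        if counts.size and (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        lib = self.library_size.reindex(counts.columns)
        if lib.isna().any():
            missing = lib.index[lib.isna()].tolist()
            raise ValidationError(f"library_size missing for datasets: {missing}")
        if (lib <= 0).any():
            raise ValidationError("library sizes must be positive")
        self.library_size = lib.astype(np.int64)
        colsum = counts.sum(axis=0)
        if (colsum > self.library_size).any():
            bad = colsum.index[(colsum > self.library_size)].tolist()
            raise ValidationError(f"column sums exceed library size for: {bad}")

    @property
    def cog_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_datasets(self, dataset_ids: Sequence[str]) -> "COGCountMatrix":
        missing = [d for d in dataset_ids if d not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown dataset ids: {missing}")
        return COGCountMatrix(
            self.counts.loc[:, list(dataset_ids)].copy(),
            self.library_size.loc[list(dataset_ids)].copy(),
        )


def validate_read_table(reads: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-read assignment table and return it unchanged.

    Requires the five canonical columns, read ids unique within each dataset,
    and recognized superkingdom labels.
    """
    missing = [c for c in READ_TABLE_COLUMNS if c not in reads.columns]
    if missing:
        raise FormatError(f"read table missing columns: {missing}")
    if reads.duplicated(subset=["dataset_id", "read_id"]).any():
        raise ValidationError("read_id values must be unique within a dataset")
    bad = set(reads["superkingdom"].unique()) - SUPERKINGDOMS
    if bad:
        raise ValidationError(f"unknown superkingdom labels: {sorted(bad)}")
    return reads


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc


def _to_int_frame(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
    arr = numeric.to_numpy()
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite count in {path}")
    if np.any(arr != np.floor(arr)):
        raise ValidationError(f"non-integer count in {path}")
    if np.any(arr < 0):
        raise ValidationError(f"negative count in {path}")
    return numeric.astype(np.int64)


def read_cog_counts(
    path: str | Path,
    format: Literal["matrix_tsv", "read_assignments_tsv"] = "matrix_tsv",
) -> COGCountMatrix:
    """Load a COG count matrix from a matrix TSV or a per-read table.

    For ``matrix_tsv`` the first column holds COG ids and the remaining
    header names are dataset ids; library size is the column sum. For
    ``read_assignments_tsv`` counts are aggregated per (COG, dataset) and the
    library size is the number of reads observed per dataset (assigned or
    not, one row per read).
    """
    if format == "matrix_tsv":
        raw = _read_tsv(path)
        if raw.shape[1] < 2:
            raise FormatError(
                f"{path}: matrix TSV needs a COG id column plus >=1 dataset column"
            )
        cog_col = raw.columns[0]
        cogs = raw[cog_col].astype(str)
        if cogs.duplicated().any():
            raise ValidationError(
                f"duplicate COG ids in {path}: {cogs[cogs.duplicated()].tolist()}"
            )
        counts = _to_int_frame(raw.drop(columns=[cog_col]), path)
        counts.index = pd.Index(cogs, name="cog_id")
        return COGCountMatrix(counts, counts.sum(axis=0))
    if format == "read_assignments_tsv":
        reads = validate_read_table(_read_tsv(path))
        return counts_from_reads(reads)
    raise FormatError(f"unknown count format {format!r}")


def counts_from_reads(reads: pd.DataFrame) -> COGCountMatrix:
    """Aggregate a validated read table into a :class:`COGCountMatrix`."""
    validate_read_table(reads)
    lib = reads.groupby("dataset_id").size()
    assigned = reads[reads["cog_id"] != ""]
    counts = (
        assigned.groupby(["cog_id", "dataset_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=lib.index, fill_value=0)
    )
    counts.index.name = "cog_id"
    return COGCountMatrix(counts.astype(np.int64), lib)


def write_cog_counts(matrix: COGCountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "cog_id"
    out.to_csv(path, sep="\t")


_META_REQUIRED = ("dataset_id", "site", "depth_m", "do_umol_kg")
_META_OPTIONAL = ("par_surface", "par_at_depth", "attenuation_k", "zone_label")


def read_metadata(path: str | Path) -> list[DatasetMetadata]:
    """Load per-dataset metadata from TSV (one row per dataset).

    Required columns: dataset_id, site, depth_m, do_umol_kg. Optional:
    par_surface, par_at_depth, attenuation_k, zone_label. Empty optional
    cells mean "absent".
    """
    raw = _read_tsv(path)
    missing = [c for c in _META_REQUIRED if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing required columns {missing}")
    if raw["dataset_id"].duplicated().any():
        dupes = raw.loc[raw["dataset_id"].duplicated(), "dataset_id"].tolist()
        raise ValidationError(f"duplicate dataset_id in {path}: {dupes}")

    def opt_float(row: pd.Series, col: str) -> float | None:
        if col not in row or row[col] == "":
            return None
        return float(row[col])

    records = []
    for _, row in raw.iterrows():
        try:
            records.append(
                DatasetMetadata(
                    dataset_id=row["dataset_id"],
                    site=row["site"],
                    depth_m=float(row["depth_m"]),
                    do_umol_kg=float(row["do_umol_kg"]),
                    par_surface=opt_float(row, "par_surface"),
                    par_at_depth=opt_float(row, "par_at_depth"),
                    attenuation_k=opt_float(row, "attenuation_k"),
                    zone_label=(row.get("zone_label") or "unset"),
                )
            )
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(
                f"{path}: bad metadata row for {row['dataset_id']!r}: {exc}"
            ) from exc
    return records


def write_metadata(records: Iterable[DatasetMetadata], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "dataset_id": rec.dataset_id,
                "site": rec.site,
                "depth_m": rec.depth_m,
                "do_umol_kg": rec.do_umol_kg,
                "par_surface": "" if rec.par_surface is None else rec.par_surface,
                "par_at_depth": "" if rec.par_at_depth is None else rec.par_at_depth,
                "attenuation_k": "" if rec.attenuation_k is None else rec.attenuation_k,
                "zone_label": rec.zone_label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_read_assignments(path: str | Path) -> pd.DataFrame:
    return validate_read_table(_read_tsv(path))


def write_read_assignments(reads: pd.DataFrame, path: str | Path) -> None:
    validate_read_table(reads)
    reads.to_csv(path, sep="\t", index=False)


def write_result(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with 12-significant-digit floats.

    If the table carries both ``p_value`` and ``p_adjusted`` columns they are
    checked for the adjusted >= raw invariant before writing.
    """
    if {"p_value", "p_adjusted"} <= set(table.columns) and len(table):
        p = table["p_value"].to_numpy(float)
        q = table["p_adjusted"].to_numpy(float)
        if np.any(q + 1e-12 < p) or np.any(q > 1.0 + 1e-12) or np.any(q < 0):
            raise ValidationError("p_adjusted must lie in [p_value, 1]")
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_result(path: str | Path) -> pd.DataFrame:
    raw = _read_tsv(path)
    out = {}
    for col in raw.columns:
        series = raw[col]
        try:
            as_num = pd.to_numeric(series)
        except (ValueError, TypeError):
            out[col] = series
        else:
            out[col] = as_num
    return pd.DataFrame(out)
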