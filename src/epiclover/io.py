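"""Reading and writing the pipeline's tabular formats.

All files are plain CSV.  The canonical dialect is comma-separated with a
"." decimal point; ``dialect=";"`` or ``dialect="\\t"`` accept the common
European export variants.  Marker matrices carry marker ids in the header
row and sample ids in the first column; subepilocus matrices add a second
header row with the methylation class of each column.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    BinaryMarkerMatrix,
    DistanceMatrix,
    SampleRecord,
    SiteRecord,
    SubepilocusMatrix,
    ValidationError,
    validate_metadata,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_marker_matrix",
    "write_marker_matrix",
    "read_metadata",
    "read_sites",
    "write_sites",
    "read_subepilocus_matrix",
    "write_subepilocus_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_releve_table",
    "read_eiv_table",
    "write_run_summary",
]

_SEPARATORS = {",": ",", ";": ";", "\t": "\t", "tab": "\t", "comma": ",", "semicolon": ";"}


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValidationError(f"unknown CSV dialect {dialect!r}; use ',', ';' or 'tab'") from None


def read_marker_matrix(path: str | Path, dialect: str = ",", label: str = "") -> BinaryMarkerMatrix:
    """Read a presence/absence matrix: header of marker ids, first column
    of sample ids, strictly 0/1 cells.  Row and column order are preserved.
    """
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            s = str(raw).strip()
            if s not in ("0", "1"):
                raise ValidationError(
                    f"{path}: non-binary cell at sample {df.index[i]!r}, "
                    f"marker {col!r}: {raw!r}"
                )
            values[i, j] = int(s)
    return BinaryMarkerMatrix(list(df.index), [str(c) for c in df.columns], values, label=label)


def write_marker_matrix(matrix: BinaryMarkerMatrix, path: str | Path, dialect: str = ",") -> None:
    df = matrix.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep(dialect))


def read_metadata(path: str | Path, dialect: str = ",",
                  allowed_habitats: Sequence[str] | None = ("CG", "OM"),
                  free_labels: bool = False) -> list[SampleRecord]:
    """Read the sample metadata table (sample_id, population_id, habitat).

    ``allowed_habitats`` restricts habitat labels unless ``free_labels`` is
    set, in which case arbitrary group labels are accepted.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    required = {"sample_id", "population_id", "habitat"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty metadata file", path)
        return []
    records = []
    for row in df.itertuples(index=False):
        hab = str(row.habitat)
        if not free_labels and allowed_habitats is not None and hab not in allowed_habitats:
            raise ValidationError(
                f"{path}: unknown habitat label {hab!r} for sample {row.sample_id!r} "
                f"(allowed: {list(allowed_habitats)}; pass free_labels=True to accept)"
            )
        records.append(SampleRecord(str(row.sample_id), str(row.population_id), hab))
    validate_metadata(records)
    return records


def read_sites(path: str | Path, dialect: str = ",") -> list[SiteRecord]:
    """Read the site table (population_id, habitat, latitude, longitude and
    optional eiv_L/eiv_M/eiv_R/eiv_N columns)."""
    df = pd.read_csv(path, sep=_sep(dialect))
    required = {"population_id", "habitat", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing site columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty site file", path)
        return []
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for name in ("eiv_L", "eiv_M", "eiv_R", "eiv_N"):
            if name in df.columns:
                v = getattr(row, name)
                kwargs[name] = None if (v is None or (isinstance(v, float) and math.isnan(v))) else float(v)
        lat, lon = float(row.latitude), float(row.longitude)
        if math.isnan(lat) or math.isnan(lon):
            raise ValidationError(f"{path}: missing coordinate for site {row.population_id!r}")
        records.append(SiteRecord(str(row.population_id), str(row.habitat), lat, lon, **kwargs))
    validate_metadata([], records)
    return records


def write_sites(sites: Sequence[SiteRecord], path: str | Path, dialect: str = ",") -> None:
    rows = []
    for s in sites:
        rows.append({
            "population_id": s.population_id, "habitat": s.habitat,
            "latitude": s.latitude, "longitude": s.longitude,
            "eiv_L": s.eiv_L, "eiv_M": s.eiv_M, "eiv_R": s.eiv_R, "eiv_N": s.eiv_N,
        })
    pd.DataFrame(rows).to_csv(path, sep=_sep(dialect), index=False, float_format="%.12g")


def write_subepilocus_matrix(sub: SubepilocusMatrix, path: str | Path, dialect: str = ",") -> None:
    """Write a subepilocus matrix with a two-row header: methylation class,
    then marker id."""
    sep = _sep(dialect)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("class" + sep + sep.join(sub.classes) + "\n")
        fh.write("sample_id" + sep + sep.join(sub.base.marker_ids) + "\n")
        for i, sid in enumerate(sub.base.sample_ids):
            fh.write(sid + sep + sep.join(str(int(v)) for v in sub.base.values[i]) + "\n")


def read_subepilocus_matrix(path: str | Path, dialect: str = ",", label: str = "MSAP-all") -> SubepilocusMatrix:
    sep = _sep(dialect)
    with open(path, encoding="utf-8") as fh:
        class_row = fh.readline().rstrip("\n").split(sep)
        header = fh.readline().rstrip("\n").split(sep)
        if class_row[0] != "class" or header[0] != "sample_id":
            raise ValidationError(f"{path}: expected 'class' and 'sample_id' header rows")
        classes = class_row[1:]
        marker_ids = header[1:]
        sample_ids, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            sample_ids.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    base = BinaryMarkerMatrix(sample_ids, marker_ids, np.array(rows, dtype=np.int8), label=label)
    # marker ids follow the "<fragment>_<class>" convention of the writer
    source = [m.rsplit("_", 1)[0] for m in marker_ids]
    return SubepilocusMatrix(base=base, classes=classes, source_fragment=source)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, dialect: str = ",") -> None:
    df = dm.to_dataframe()
    df.index.name = "id"
    df.to_csv(path, sep=_sep(dialect), float_format="%.12g")


def read_distance_matrix(path: str | Path, dialect: str = ",", name: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    return DistanceMatrix.from_dataframe(df, name=name)


def read_releve_table(path: str | Path, dialect: str = ",") -> pd.DataFrame:
    """Vegetation relevé table: sites in rows, species in columns,
    non-negative abundances (any cover scale)."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError(f"{path}: missing abundance cells (use 0 for absence)")
    if (arr < 0).any():
        raise ValidationError(f"{path}: negative abundances")
    return df


def read_eiv_table(path: str | Path, dialect: str = ",") -> pd.DataFrame:
    """Species indicator-value table with columns L, M, R, N; the marker
    ``x`` (or empty) denotes an indifferent species and becomes NaN."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    cols = [c for c in ("L", "M", "R", "N") if c in df.columns]
    if not cols:
        raise ValidationError(f"{path}: no indicator columns among L, M, R, N")
    out = pd.DataFrame(index=df.index)
    for c in cols:
        vals = []
        for raw in df[c]:
            s = str(raw).strip().lower()
            if s in ("x", "", "nan", "none"):
                vals.append(np.nan)
            else:
                v = float(s)
                if not 1.0 <= v <= 9.0:
                    raise ValidationError(f"{path}: indicator value {v} outside [1, 9] in column {c}")
                vals.append(v)
        out[c] = vals
    return out


def write_run_summary(path: str | Path, summary: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
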