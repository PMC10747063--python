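"""Reading, validating and writing peptidoform peak-area tables.

The native interchange format is a flat text table (TSV or CSV) with one row
per quantified peptidoform observation:

==============  =======================================================
column          content
==============  =======================================================
sample_group    biological group label (e.g. ``7ds``, ``cR``, ``TSA-cS``)
replicate       positive integer replicate index within the group
region_id       peptide region label (see :mod:`histoptm.regions`)
modifications   compact ``site:mark`` annotation ("" = unmodified)
peak_area       non-negative EIC peak area (arbitrary intensity units)
==============  =======================================================

In memory, a *record collection* is a :class:`pandas.DataFrame` with exactly
these columns and canonicalized modification strings; :func:`to_records` and
:func:`from_records` convert to/from :class:`PeptidoformRecord` dataclasses for
row-level work.  All writers emit UTF-8, tab-delimited text with "." as the
decimal separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .regions import (
    ModificationState,
    ValidationError,
    format_modstring,
    get_region,
    parse_modstring,
)

logger = logging.getLogger("histoptm")

COLUMNS: tuple[str, ...] = (
    "sample_group",
    "replicate",
    "region_id",
    "modifications",
    "peak_area",
)


class SchemaError(ValidationError):
    """The input table does not expose the mandatory columns."""


@dataclass(frozen=True)
class PeptidoformRecord:
    """One quantified modified-peptide observation."""

    sample_group: str
    replicate: int
    region_id: str
    modstate: ModificationState
    peak_area: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if not self.peak_area >= 0:
            raise ValidationError(f"peak_area must be >= 0, got {self.peak_area}")


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a YAML column-name mapping ``{canonical_name: file_column}``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(COLUMNS)
    if unknown:
        raise SchemaError(f"schema maps unknown canonical column(s): {sorted(unknown)}")
    return {str(k): str(v) for k, v in raw.items()}


def _infer_sep(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in {".tsv", ".tab", ".txt"}:
        return "\t"
    # sniff the header line
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_peak_area_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and canonicalize a peptidoform peak-area table.

    Parameters
    ----------
    path:
        TSV or CSV file (dialect inferred from the extension unless *sep* is
        given).
    schema:
        Optional mapping of canonical column names onto the file's column
        names, e.g. ``{"peak_area": "Total Area"}``.

    Returns
    -------
    pandas.DataFrame
        Canonical record collection (columns as in :data:`COLUMNS`), with
        modification strings rewritten in canonical form.

    Raises
    ------
    SchemaError
        A mandatory column is missing.
    ValidationError
        Empty file, non-numeric/negative area (with the offending row number),
        or duplicate (sample, replicate, region, form) rows.
    """
    path = Path(path)
    sep = sep or _infer_sep(path)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if raw.empty:
        raise ValidationError(f"{path}: table has a header but no rows")

    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    records = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # 1 = header
        region = get_region(getattr(row, "region_id"))
        area_text = getattr(row, "peak_area")
        try:
            area = float(area_text)
        except ValueError:
            raise ValidationError(
                f"{path}: non-numeric peak_area {area_text!r} on row {i}"
            ) from None
        if area < 0:
            raise ValidationError(f"{path}: negative peak_area on row {i}")
        try:
            rep = int(getattr(row, "replicate"))
        except ValueError:
            raise ValidationError(
                f"{path}: non-integer replicate on row {i}"
            ) from None
        state = parse_modstring(getattr(row, "modifications"), region)
        records.append(
            (getattr(row, "sample_group"), rep, region.region_id,
             format_modstring(state), area)
        )

    df = pd.DataFrame.from_records(records, columns=COLUMNS)
    dup = df.duplicated(subset=COLUMNS[:4], keep=False)
    if dup.any():
        keys = df.loc[dup, list(COLUMNS[:4])].drop_duplicates()
        raise ValidationError(
            f"{path}: duplicate rows after canonicalization for keys:\n"
            f"{keys.to_string(index=False)}"
        )
    return df


def write_peak_area_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical record collection as UTF-8 tab-delimited text."""
    df.loc[:, list(COLUMNS)].to_csv(path, sep="\t", index=False, encoding="utf-8")


def to_records(df: pd.DataFrame) -> list[PeptidoformRecord]:
    """Materialize a record DataFrame as dataclass instances."""
    out = []
    for row in df.itertuples(index=False):
        region = get_region(row.region_id)
        out.append(
            PeptidoformRecord(
                sample_group=row.sample_group,
                replicate=int(row.replicate),
                region_id=row.region_id,
                modstate=parse_modstring(row.modifications, region),
                peak_area=float(row.peak_area),
            )
        )
    return out


def from_records(records: Iterable[PeptidoformRecord]) -> pd.DataFrame:
    rows = [
        (r.sample_group, r.replicate, r.region_id,
         format_modstring(r.modstate), r.peak_area)
        for r in records
    ]
    return pd.DataFrame.from_records(rows, columns=COLUMNS)


def merge_groups(
    df: pd.DataFrame,
    sources: Sequence[str],
    target: str,
) -> pd.DataFrame:
    """Pool source groups into one target group, summing areas per replicate.

    Replicate *i* of each source is treated as one part of the same pooled
    biological sample (e.g. root and shoot halves of one seedling batch), so
    areas are summed per (replicate, region, form).  Forms or replicates seen
    in only one source are kept with the available areas rather than dropped,
    mirroring uneven detection between tissues.

    Raises
    ------
    ValidationError
        If *target* already exists, a source is missing, or a source is
        repeated (merging a group with itself is meaningless).
    """
    sources = list(sources)
    if len(set(sources)) != len(sources):
        raise ValidationError("duplicate labels in merge sources")
    if len(sources) < 2:
        raise ValidationError("need at least two source groups to merge")
    present = set(df["sample_group"])
    missing = [s for s in sources if s not in present]
    if missing:
        raise ValidationError(f"source group(s) not in table: {missing}")
    if target in present:
        raise ValidationError(f"target group {target!r} already present")

    mask = df["sample_group"].isin(sources)
    merged = (
        df.loc[mask]
        .groupby(["replicate", "region_id", "modifications"], as_index=False)["peak_area"]
        .sum()
    )
    merged.insert(0, "sample_group", target)
    logger.info(
        "merged %s -> %s by summing areas per replicate/region/form", sources, target
    )
    rest = df.loc[~mask]
    return pd.concat([rest, merged[list(COLUMNS)]], ignore_index=True)
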