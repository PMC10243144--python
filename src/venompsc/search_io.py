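"""Ingestion and merging of per-well protein search-engine exports.

Each well of a nanofractionated plate is digested and searched
independently, producing one export table of protein hits per well
(accession, score, coverage, mass, description, peptides, ...).  A
separate job -> well map records which search job belongs to which
well.  This module parses those exports, de-duplicates hits within a
well, attaches the well's fractionation retention time and merges
everything into one retention-time-sorted table — the tabular backbone
of all downstream chromatogram building.

Canonical export columns (header required)::

    accession, score, coverage_pct, mass_da, description, species,
    sequence, peptides, link

``peptides`` is a semicolon-joined list.  Real search-engine headers
can be adapted with a column-alias map.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .platemap import FractionSchedule, PlateLayout, fraction_to_rt, run_well_ids

__all__ = [
    "SearchHit",
    "SearchExportError",
    "CANONICAL_COLUMNS",
    "read_job_well_map",
    "parse_search_export",
    "read_export_dir",
    "merge_wells",
    "write_merged",
    "read_merged",
    "write_merged_excel",
]

logger = logging.getLogger(__name__)


class SearchExportError(ValueError):
    """Malformed export or job map."""


CANONICAL_COLUMNS = [
    "accession",
    "score",
    "coverage_pct",
    "mass_da",
    "description",
    "species",
    "sequence",
    "peptides",
    "link",
]

_REQUIRED_COLUMNS = ["accession", "score"]

MERGED_COLUMNS = ["rt_min", "well_id"] + CANONICAL_COLUMNS


@dataclass(frozen=True)
class SearchHit:
    """One protein identification in one well."""

    well_id: str
    accession: str
    protein_score: float
    sequence_coverage: float = 0.0
    protein_mass: float = float("nan")
    description: str = ""
    species: str = ""
    full_sequence: str = ""
    peptides: tuple[str, ...] = ()
    search_link: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if self.protein_score < 0:
            raise ValueError("protein_score must be >= 0")
        if not (0.0 <= self.sequence_coverage <= 100.0):
            raise ValueError("sequence_coverage must lie in [0, 100]")


def read_job_well_map(
    source, layout: PlateLayout | None = None
) -> dict[str, str]:
    """Read a two-column job -> well CSV (columns ``job_id, well_id``).

    Duplicate job ids raise :class:`SearchExportError`; a well id that
    does not exist on *layout* (when given) raises too.  An empty table
    yields an empty mapping with a warning.
    """
    df = pd.read_csv(source, dtype=str)
    missing = [c for c in ("job_id", "well_id") if c not in df.columns]
    if missing:
        raise SearchExportError(f"job map missing column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("job->well map is empty")
        return {}
    jobs = df["job_id"].astype(str).str.strip()
    dup = jobs[jobs.duplicated()].unique()
    if len(dup):
        raise SearchExportError(f"duplicate job id(s) in map: {', '.join(dup)}")
    mapping: dict[str, str] = {}
    for job, well in zip(jobs, df["well_id"].astype(str).str.strip()):
        if layout is not None:
            layout.parse_well_id(well)  # raises on bad well
        mapping[job] = well.upper()
    return mapping


def parse_search_export(
    source,
    well_id: str,
    column_aliases: Mapping[str, str] | None = None,
) -> list[SearchHit]:
    """Parse one per-well export into :class:`SearchHit` records.

    Rows with a missing accession or a non-numeric score are dropped
    (and counted in a log message).  If the same accession appears more
    than once in a well, only the highest-scoring record is kept —
    duplicate records are a symptom of a malformed export, and search
    scores are not additive evidence.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if column_aliases:
        df = df.rename(columns=dict(column_aliases))
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SearchExportError(
            f"export for well {well_id} missing column(s): {', '.join(missing)}"
        )
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    n_dropped = 0
    best: dict[str, SearchHit] = {}
    for row in df.itertuples(index=False):
        acc = str(row.accession).strip()
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            score = float("nan")
        if not acc or not score == score or score < 0:
            n_dropped += 1
            continue
        coverage = _float_or(row.coverage_pct, 0.0)
        mass = _float_or(row.mass_da, float("nan"))
        peptides = tuple(p for p in str(row.peptides).split(";") if p)
        hit = SearchHit(
            well_id=well_id,
            accession=acc,
            protein_score=score,
            sequence_coverage=coverage,
            protein_mass=mass,
            description=str(row.description),
            species=str(row.species),
            full_sequence=str(row.sequence),
            peptides=peptides,
            search_link=str(row.link),
        )
        prev = best.get(acc)
        if prev is None or hit.protein_score > prev.protein_score:
            best[acc] = hit
    if n_dropped:
        logger.info("well %s: dropped %d malformed row(s)", well_id, n_dropped)
    return list(best.values())


def _float_or(value, default: float) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        return default
    return out if out == out else default


def read_export_dir(
    export_dir: str | Path,
    job_map: Mapping[str, str],
    column_aliases: Mapping[str, str] | None = None,
) -> dict[str, list[SearchHit]]:
    """Read every ``<job_id>.csv`` named in *job_map* from a directory.

    Files absent from the directory are reported as unmapped jobs and
    skipped; extra files are ignored.
    """
    export_dir = Path(export_dir)
    per_well: dict[str, list[SearchHit]] = {}
    missing_jobs = []
    for job, well in job_map.items():
        path = export_dir / f"{job}.csv"
        if not path.is_file():
            missing_jobs.append(job)
            continue
        per_well[well] = parse_search_export(path, well, column_aliases)
    if missing_jobs:
        logger.warning("no export file for job(s): %s", ", ".join(missing_jobs))
    return per_well


def merge_wells(
    per_well_hits: Mapping[str, Iterable[SearchHit]],
    schedule: FractionSchedule,
    layout: PlateLayout,
    run_index: int = 1,
) -> pd.DataFrame:
    """Merge per-well hits into one retention-time-sorted table.

    One row per (well, accession), ordered by the well's fraction
    index; wells without hits contribute no rows.  The result is
    independent of the input ordering of wells.  A hit in a well that
    does not belong to run *run_index* raises
    :class:`~venompsc.platemap.PlateCapacityError` via lookup failure.
    """
    order = {w: i + 1 for i, w in enumerate(run_well_ids(layout, schedule, run_index))}
    records = []
    for well, hits in per_well_hits.items():
        well = well.upper()
        if well not in order:
            raise SearchExportError(
                f"well {well} is not part of run {run_index} under this schedule"
            )
        frac = order[well]
        rt = fraction_to_rt(schedule, frac)
        for hit in hits:
            records.append(
                {
                    "rt_min": rt,
                    "well_id": well,
                    "accession": hit.accession,
                    "score": hit.protein_score,
                    "coverage_pct": hit.sequence_coverage,
                    "mass_da": hit.protein_mass,
                    "description": hit.description,
                    "species": hit.species,
                    "sequence": hit.full_sequence,
                    "peptides": ";".join(hit.peptides),
                    "link": hit.search_link,
                }
            )
    df = pd.DataFrame.from_records(records, columns=MERGED_COLUMNS)
    df = df.sort_values(["rt_min", "accession"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(["well_id", "accession"])
    if dup.any():
        raise SearchExportError("duplicate (well, accession) pairs after merge")
    return df


def write_merged(table: pd.DataFrame, path: str | Path) -> None:
    """Write the merged table as UTF-8 CSV (the canonical format)."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_merged(path) -> pd.DataFrame:
    """Read a merged table back; inverse of :func:`write_merged`."""
    df = pd.read_csv(
        path,
        encoding="utf-8",
        dtype={c: str for c in ("well_id", "accession", "description", "species",
                                "sequence", "peptides", "link")},
        keep_default_na=False,
    )
    missing = [c for c in MERGED_COLUMNS if c not in df.columns]
    if missing:
        raise SearchExportError(f"merged table missing column(s): {', '.join(missing)}")
    for col in ("rt_min", "score", "coverage_pct", "mass_da"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[MERGED_COLUMNS]


def write_merged_excel(table: pd.DataFrame, path: str | Path) -> None:
    """Optional spreadsheet writer for the merged table."""
    table.to_excel(path, index=False)
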