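"""Protein Score Chromatograms and related per-fraction traces.

A Protein Score Chromatogram (PSC) plots one protein's search-engine
score per fraction against that fraction's retention time, giving a
chromatogram-like elution profile reconstructed purely from proteomics
evidence.  Variants built here:

* PSC  — score per fraction for one accession
* SCC  — sequence-coverage per fraction for one accession
* TPC  — total protein chromatogram, the sum of all scores per
  fraction (the proteomics analogue of a total ion chromatogram)

Fractions where a protein was not identified are filled with 0, so the
trace returns to baseline like a real chromatogram.  No smoothing or
interpolation is applied: values are the raw per-well scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .platemap import FractionSchedule, rt_grid

__all__ = [
    "PSCTrace",
    "GridMismatchError",
    "build_psc",
    "build_scc",
    "build_tpc",
    "combine_traces",
    "traces_long_frame",
    "plot_traces",
]


class GridMismatchError(ValueError):
    """Traces do not share a common retention-time grid."""


@dataclass(frozen=True)
class PSCTrace:
    """A per-fraction (retention time, value) series for one protein.

    ``value_kind`` is ``"score"`` for a PSC or TPC and ``"coverage"``
    for an SCC.  The grid covers every fraction of the run, with zeros
    where the protein was not identified.
    """

    accession: str
    description: str
    rt_min: tuple[float, ...]
    values: tuple[float, ...]
    value_kind: str = "score"

    def __post_init__(self) -> None:
        if len(self.rt_min) != len(self.values):
            raise ValueError("rt grid and values differ in length")
        if self.value_kind not in ("score", "coverage"):
            raise ValueError(f"unknown value kind: {self.value_kind!r}")
        if any(v < 0 for v in self.values):
            raise ValueError("trace values must be >= 0")

    @property
    def total(self) -> float:
        return float(np.sum(self.values))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.rt_min, float), np.asarray(self.values, float)


def _well_value_map(table: pd.DataFrame, accession: str, column: str) -> dict[float, float]:
    sub = table[table["accession"] == accession]
    return dict(zip(sub["rt_min"].astype(float), sub[column].astype(float)))


def build_psc(
    table: pd.DataFrame, accession: str, schedule: FractionSchedule
) -> PSCTrace:
    """Build the score chromatogram of one accession from a merged table.

    Every fraction of the run appears on the grid; fractions where the
    accession was not found carry value 0.  An accession absent from
    the table yields an all-zero trace.
    """
    return _build_single(table, accession, schedule, "score", "score")


def build_scc(
    table: pd.DataFrame, accession: str, schedule: FractionSchedule
) -> PSCTrace:
    """Sequence Coverage Chromatogram: like :func:`build_psc` but the
    y-values are percent sequence coverage."""
    return _build_single(table, accession, schedule, "coverage_pct", "coverage")


def _build_single(table, accession, schedule, column, kind) -> PSCTrace:
    grid = rt_grid(schedule)
    lookup = _well_value_map(table, accession, column)
    values = tuple(float(lookup.get(rt, 0.0)) for rt in grid)
    desc = ""
    sub = table[table["accession"] == accession]
    if len(sub):
        desc = str(sub["description"].iloc[0])
    return PSCTrace(
        accession=accession,
        description=desc,
        rt_min=tuple(grid),
        values=values,
        value_kind=kind,
    )


def build_tpc(table: pd.DataFrame, schedule: FractionSchedule) -> PSCTrace:
    """Total Protein Chromatogram: per-fraction sum of all scores.

    Conserves total score exactly: the trace sums to the sum of the
    ``score`` column of the merged table.
    """
    grid = rt_grid(schedule)
    sums = table.groupby("rt_min")["score"].sum() if len(table) else pd.Series(dtype=float)
    lookup = {float(k): float(v) for k, v in sums.items()}
    values = tuple(lookup.get(rt, 0.0) for rt in grid)
    return PSCTrace(
        accession="TPC",
        description="total protein chromatogram",
        rt_min=tuple(grid),
        values=values,
        value_kind="score",
    )


def combine_traces(traces: list[PSCTrace]) -> pd.DataFrame:
    """Wide table with the shared rt grid and one column per accession.

    Columns are ordered by descending total trace value, ties broken by
    accession (lexicographic), so the most abundant proteins come
    first and the layout is deterministic.  Traces must share one grid.
    """
    if not traces:
        return pd.DataFrame({"rt_min": []})
    grid = traces[0].rt_min
    for t in traces[1:]:
        if t.rt_min != grid:
            raise GridMismatchError(
                f"trace {t.accession} is on a different rt grid"
            )
    ordered = sorted(traces, key=lambda t: (-t.total, t.accession))
    data = {"rt_min": list(grid)}
    for t in ordered:
        data[t.accession] = list(t.values)
    return pd.DataFrame(data)


def traces_long_frame(traces: list[PSCTrace]) -> pd.DataFrame:
    """Long-format export: accession, rt_min, value, value_kind."""
    records = []
    for t in traces:
        for rt, v in zip(t.rt_min, t.values):
            records.append(
                {"accession": t.accession, "rt_min": rt, "value": v,
                 "value_kind": t.value_kind}
            )
    return pd.DataFrame.from_records(
        records, columns=["accession", "rt_min", "value", "value_kind"]
    )


def plot_traces(traces: list[PSCTrace], path=None, title: str = ""):
    """Overlaid line plot of traces, one colour per accession.

    Returns the matplotlib figure; saves to *path* when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for t in traces:
        rt, v = t.as_arrays()
        ax.plot(rt, v, label=t.accession, linewidth=1.0)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("protein score" if all(t.value_kind == "score" for t in traces)
                  else "value")
    if title:
        ax.set_title(title)
    if traces and len(traces) <= 15:
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
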