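"""Correlation of PSC peaks with intact-mass XICs and UV traces.

The nanofractionation platform records an intact-protein MS run in
parallel with fraction collection, so each deconvoluted accurate mass
yields an extracted ion chromatogram (XIC) on a fine time grid.  A PSC
peak whose retention time and peak shape match an XIC links a bottom-up
identification to an intact mass.  When one accession elutes as several
PSC peaks, the matched masses discriminate between genuinely different
proteoforms (distinct masses -> PTM or isoform candidate) and an
artifact of conserved tryptic peptides shared between homologues (the
same mass under every peak).

Shape similarity is the Pearson correlation of the two traces after
resampling onto the PSC fraction grid, restricted to the peak window
plus one fraction on each side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import PSCPeak
from .psc import PSCTrace

__all__ = [
    "XICTrace",
    "PeakMatch",
    "IsoformAnnotation",
    "resample_to_grid",
    "shape_similarity",
    "match_psc_xic",
    "annotate_isoforms",
    "matches_frame",
    "read_xic_csv",
    "read_uv_csv",
    "plot_superimposed",
]


@dataclass(frozen=True)
class XICTrace:
    """Extracted ion chromatogram for one accurate mass.

    ``label`` is the deconvoluted intact mass in Da, kept as text
    (it identifies the trace, it is not computed on); points are
    (rt_min, intensity) with strictly increasing rt.
    """

    label: str
    rt_min: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt_min, float)
        if len(rt) != len(self.intensity):
            raise ValueError("rt and intensity differ in length")
        if len(rt) > 1 and not np.all(np.diff(rt) > 0):
            raise ValueError("rt must be strictly increasing")
        if any(v < 0 for v in self.intensity):
            raise ValueError("intensity must be >= 0")

    @property
    def mass_da(self) -> float:
        return float(self.label)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.rt_min, float), np.asarray(self.intensity, float)


@dataclass(frozen=True)
class PeakMatch:
    """An accepted pairing of a PSC peak with an XIC."""

    accession: str
    psc_peak: PSCPeak
    xic_label: str
    rt_delta_min: float
    shape_similarity: float


@dataclass(frozen=True)
class IsoformAnnotation:
    """Proteoform verdict for one accession across its PSC peaks.

    Verdicts: ``single_form`` (one peak), ``multiple_masses_candidate_
    PTM_or_isoform`` (>= 2 peaks carrying distinct matched masses, with
    all pairwise mass deltas reported), ``shared_peptide_artifact_
    suspected`` (>= 2 peaks all matched to the same mass — the classic
    signature of conserved peptides mapping to one homologue), and
    ``unresolved_multiple_peaks`` when several peaks lack the mass
    evidence to decide.
    """

    accession: str
    n_peaks: int
    peak_masses: tuple[tuple[float, ...], ...]  # matched masses per peak
    mass_deltas_da: tuple[float, ...]
    verdict: str


def resample_to_grid(rt, values, grid) -> np.ndarray:
    """Linear interpolation of a trace onto a target rt grid.

    Grid points outside the source range map to 0 (baseline).  Fewer
    than two source points is a degenerate trace and raises.
    """
    rt = np.asarray(rt, float)
    values = np.asarray(values, float)
    if rt.size < 2:
        raise ValueError("cannot resample a trace with fewer than 2 points")
    return np.interp(np.asarray(grid, float), rt, values, left=0.0, right=0.0)


def shape_similarity(a, b) -> float:
    """Pearson correlation of two equally sampled windows, in [-1, 1].

    Returns ``nan`` when either window has zero variance (similarity is
    undefined for a flat trace).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("windows must have equal length")
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, r))


def match_psc_xic(
    psc_peaks: list[PSCPeak],
    psc_traces: dict[str, PSCTrace],
    xic_traces: list[XICTrace],
    rt_tolerance_min: float = 0.1,
    min_similarity: float = 0.7,
) -> list[PeakMatch]:
    """Match each PSC peak against every XIC by apex time and shape.

    The XIC apex for a peak is the XIC's global maximum within the peak
    window widened by the tolerance.  An XIC matches when that apex
    lies within ``rt_tolerance_min`` of the PSC apex and the windowed
    shape similarity is at least ``min_similarity``.  A peak may match
    several XICs; matches are returned ranked by descending similarity
    within each peak.
    """
    matches: list[PeakMatch] = []
    for peak in psc_peaks:
        trace = psc_traces[peak.accession]
        grid, psc_vals = trace.as_arrays()
        step = float(grid[1] - grid[0]) if len(grid) > 1 else 0.1
        window = (grid >= peak.rt_start - step) & (grid <= peak.rt_end + step)
        peak_matches = []
        for xic in xic_traces:
            xrt, xint = xic.as_arrays()
            sel = (xrt >= peak.rt_start - rt_tolerance_min) & (
                xrt <= peak.rt_end + rt_tolerance_min
            )
            if not sel.any() or xint[sel].max() <= 0:
                continue
            local = np.flatnonzero(sel)
            apex_idx = local[int(np.argmax(xint[local]))]
            delta = float(xrt[apex_idx] - peak.apex_rt)
            if abs(delta) > rt_tolerance_min:
                continue
            xic_on_grid = resample_to_grid(xrt, xint, grid[window])
            sim = shape_similarity(psc_vals[window], xic_on_grid)
            if sim == sim and sim >= min_similarity:
                peak_matches.append(
                    PeakMatch(
                        accession=peak.accession,
                        psc_peak=peak,
                        xic_label=xic.label,
                        rt_delta_min=delta,
                        shape_similarity=sim,
                    )
                )
        peak_matches.sort(key=lambda m: (-m.shape_similarity, abs(m.rt_delta_min)))
        matches.extend(peak_matches)
    return matches


def annotate_isoforms(
    accession: str,
    peaks: list[PSCPeak],
    matches: list[PeakMatch],
    mass_tolerance_da: float = 1.0,
) -> IsoformAnnotation:
    """Proteoform verdict for one accession from its peak/mass matches.

    Masses differing by more than ``mass_tolerance_da`` count as
    distinct.  See :class:`IsoformAnnotation` for the verdict rules.
    """
    peaks = [p for p in peaks if p.accession == accession]
    peaks.sort(key=lambda p: p.rt_start)
    per_peak_masses: list[tuple[float, ...]] = []
    for p in peaks:
        ms = sorted(
            {float(m.xic_label) for m in matches
             if m.accession == accession and m.psc_peak == p}
        )
        per_peak_masses.append(tuple(ms))

    best = [ms[0] if ms else None for ms in per_peak_masses]
    observed = [m for m in best if m is not None]
    distinct: list[float] = []
    for m in observed:
        if all(abs(m - d) > mass_tolerance_da for d in distinct):
            distinct.append(m)
    deltas = tuple(
        round(abs(b - a), 6) for a, b in itertools.combinations(sorted(distinct), 2)
    )

    if len(peaks) <= 1:
        verdict = "single_form"
    elif len(distinct) >= 2:
        verdict = "multiple_masses_candidate_PTM_or_isoform"
    elif len(observed) >= 2 and len(distinct) == 1:
        verdict = "shared_peptide_artifact_suspected"
    else:
        # several peaks but <2 with usable masses: no mass evidence either way
        verdict = "unresolved_multiple_peaks"
    return IsoformAnnotation(
        accession=accession,
        n_peaks=len(peaks),
        peak_masses=tuple(per_peak_masses),
        mass_deltas_da=deltas,
        verdict=verdict,
    )


def matches_frame(matches: list[PeakMatch]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "accession": m.accession,
                "apex_rt": m.psc_peak.apex_rt,
                "xic_label": m.xic_label,
                "rt_delta_min": m.rt_delta_min,
                "shape_similarity": m.shape_similarity,
            }
            for m in matches
        ],
        columns=["accession", "apex_rt", "xic_label", "rt_delta_min", "shape_similarity"],
    )


def read_xic_csv(path) -> list[XICTrace]:
    """Read long-format XIC CSV (columns label, rt_min, intensity)."""
    df = pd.read_csv(path, dtype={"label": str})
    traces = []
    for label, sub in df.groupby("label", sort=True):
        sub = sub.sort_values("rt_min")
        traces.append(
            XICTrace(
                label=str(label),
                rt_min=tuple(sub["rt_min"].astype(float)),
                intensity=tuple(sub["intensity"].astype(float)),
            )
        )
    return traces


def read_uv_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a UV trace CSV (columns rt_min, absorbance)."""
    df = pd.read_csv(path)
    df = df.sort_values("rt_min")
    return df["rt_min"].to_numpy(float), df["absorbance"].to_numpy(float)


def plot_superimposed(
    psc_traces: list[PSCTrace],
    xic_traces: list[XICTrace] | None = None,
    uv: tuple[np.ndarray, np.ndarray] | None = None,
    tpc: PSCTrace | None = None,
    path=None,
    title: str = "",
):
    """Stacked panels sharing one rt axis: UV, TPC, XICs, PSCs.

    PSC values stay on their fraction midpoints — no resampling — so
    the panels can be compared without interpolation artifacts.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("PSC", psc_traces)]
    if xic_traces:
        panels.insert(0, ("XIC", xic_traces))
    if tpc is not None:
        panels.insert(0, ("TPC", [tpc]))
    if uv is not None:
        panels.insert(0, ("UV", uv))
    fig, axes = plt.subplots(len(panels), 1, sharex=True,
                             figsize=(9, 2.2 * len(panels)), squeeze=False)
    for ax, (kind, payload) in zip(axes[:, 0], panels):
        if kind == "UV":
            ax.plot(payload[0], payload[1], color="black", linewidth=0.8)
            ax.set_ylabel("UV (AU)")
        elif kind in ("PSC", "TPC"):
            for t in payload:
                rt, v = t.as_arrays()
                ax.plot(rt, v, linewidth=1.0, label=t.accession)
            ax.set_ylabel("score")
            if kind == "PSC" and len(payload) <= 12:
                ax.legend(fontsize=6)
        else:
            for x in payload:
                rt, v = x.as_arrays()
                ax.plot(rt, v, linewidth=0.8, label=x.label)
            ax.set_ylabel("XIC")
            if len(payload) <= 12:
                ax.legend(fontsize=6)
    axes[-1, 0].set_xlabel("retention time (min)")
    if title:
        axes[0, 0].set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
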