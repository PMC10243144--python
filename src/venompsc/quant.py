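"""Peak detection, integration and toxin-family semiquantitation.

Protein Score Chromatograms are sampled once per fraction, so "peaks"
are runs of consecutive fractions with nonzero score.  Two knobs shape
the peak definition:

* ``gap_tolerance`` — up to this many interior zero fractions (single
  dropout wells, typically) are absorbed into one peak instead of
  splitting it;
* ``split_ratio`` — a run containing two local maxima is split at the
  interior minimum when that minimum falls below ``split_ratio`` times
  the smaller of the two maxima, so partially resolved isoforms become
  separate peaks.

Areas are trapezoidal in score·minutes, with zero-valued anchor points
one fraction interval outside each bound: wells are treated as point
samples of an elution profile, which gives a single-well protein a
triangular (nonzero) area instead of zero.

Relative venom composition is reported per toxin family (SVMP, SVSP,
PLA2, CTL, LAAO, 3FTx, CRISP, Kunitz-type inhibitors, disintegrins, or
"other"), either from PSC peak areas or from summed protein scores.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .psc import PSCTrace

__all__ = [
    "PSCPeak",
    "FamilyQuant",
    "UVMatch",
    "DEFAULT_FAMILY_RULES",
    "detect_peaks",
    "integrate_peak",
    "summed_score",
    "classify_family",
    "family_abundance",
    "match_uv_peaks",
    "peaks_frame",
    "family_frame",
    "plot_family_pie",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSCPeak:
    """One integrated chromatographic peak of a PSC.

    Bounds are inclusive fraction midpoints; ``n_fractions`` counts the
    grid points inside the bounds (including any tolerated interior
    zero fractions).
    """

    accession: str
    rt_start: float
    rt_end: float
    apex_rt: float
    apex_value: float
    area: float
    n_fractions: int

    def __post_init__(self) -> None:
        if not (self.rt_start <= self.apex_rt <= self.rt_end):
            raise ValueError("apex must lie within peak bounds")
        if self.area <= 0:
            raise ValueError("peak area must be positive")


@dataclass(frozen=True)
class FamilyQuant:
    """Total quantity and normalized fraction for one toxin family."""

    family: str
    total: float
    fraction: float


@dataclass(frozen=True)
class UVMatch:
    """Pairing of a PSC peak with a UV absorbance peak."""

    accession: str
    psc_apex_rt: float
    uv_apex_rt: float | None
    uv_area: float | None
    status: str  # matched | unmatched | ambiguous


# Ordered (regex, family) rules; first match wins, so e.g.
# "Zinc metalloproteinase/disintegrin" classifies as SVMP.
DEFAULT_FAMILY_RULES: list[tuple[str, str]] = [
    (r"metalloprotein|reprolysin|svmp", "SVMP"),
    (r"phospholipase\s*a2|\bpla2\b", "PLA2"),
    (r"serine\s*prote(in)?ase|thrombin[- ]like|\bsvsp\b", "SVSP"),
    (r"c[- ]type\s*lectin|snaclec|\bctl\b", "CTL"),
    (r"amino[- ]acid\s*oxidase|\blaao\b", "LAAO"),
    (r"three[- ]finger|\b3ftx\b|cytotoxin|cardiotoxin|alpha[- ]neurotoxin", "3FTx"),
    (r"cysteine[- ]rich\s*secretory|\bcrisp\b", "CRISP"),
    (r"kunitz|protease\s*inhibitor", "VKTI"),
    (r"disintegrin", "disintegrin"),
]


def detect_peaks(
    trace: PSCTrace,
    gap_tolerance: int = 1,
    split_ratio: float = 0.5,
) -> list[PSCPeak]:
    """Find and integrate the peaks of a per-fraction trace.

    Peaks are maximal runs of nonzero values, allowing up to
    ``gap_tolerance`` consecutive interior zeros, then valley-split
    between local maxima (see module docstring).  Returned ordered by
    ``rt_start``; an all-zero trace yields an empty list.
    """
    rt, values = trace.as_arrays()
    runs = _nonzero_runs(values, gap_tolerance)
    segments: list[tuple[int, int]] = []
    for lo, hi in runs:
        segments.extend(_valley_split(values, lo, hi, split_ratio))
    peaks = []
    for lo, hi in segments:
        seg = values[lo : hi + 1]
        apex_off = int(np.argmax(seg))
        peaks.append(
            PSCPeak(
                accession=trace.accession,
                rt_start=float(rt[lo]),
                rt_end=float(rt[hi]),
                apex_rt=float(rt[lo + apex_off]),
                apex_value=float(seg[apex_off]),
                area=_trapezoid_area(rt, values, lo, hi),
                n_fractions=hi - lo + 1,
            )
        )
    return peaks


def _nonzero_runs(values: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal index ranges of nonzero values, bridging short zero gaps."""
    nz = np.flatnonzero(values > 0)
    if nz.size == 0:
        return []
    runs = []
    lo = prev = int(nz[0])
    for i in nz[1:]:
        i = int(i)
        if i - prev - 1 > gap_tolerance:
            runs.append((lo, prev))
            lo = i
        prev = i
    runs.append((lo, prev))
    return runs


def _valley_split(
    values: np.ndarray, lo: int, hi: int, split_ratio: float
) -> list[tuple[int, int]]:
    """Split [lo, hi] at valleys deeper than split_ratio of the smaller
    flanking maximum; the valley fraction joins the left segment."""
    seg = values[lo : hi + 1]
    if len(seg) < 3:
        return [(lo, hi)]
    # pad so boundary maxima are found
    maxima, _ = find_peaks(np.concatenate(([-1.0], seg, [-1.0])))
    maxima = maxima - 1
    if len(maxima) < 2:
        return [(lo, hi)]
    for m1, m2 in zip(maxima[:-1], maxima[1:]):
        valley = m1 + 1 + int(np.argmin(seg[m1 + 1 : m2]))
        # zero valleys are dropout wells governed by gap_tolerance, not splits
        if 0 < seg[valley] < split_ratio * min(seg[m1], seg[m2]):
            left = _valley_split(values, lo, lo + valley, split_ratio)
            right = _valley_split(values, lo + valley + 1, hi, split_ratio)
            return left + right
    return [(lo, hi)]


def _trapezoid_area(rt: np.ndarray, values: np.ndarray, lo: int, hi: int) -> float:
    """Trapezoid over [lo, hi] with zero anchors one grid step outside."""
    if hi == lo:
        dt = _grid_step(rt, lo)
        return float(values[lo]) * dt  # two triangles of base dt/... = v*dt
    x = rt[lo : hi + 1]
    y = values[lo : hi + 1]
    dt_left = _grid_step(rt, lo)
    dt_right = _grid_step(rt, hi)
    x = np.concatenate(([x[0] - dt_left], x, [x[-1] + dt_right]))
    y = np.concatenate(([0.0], y, [0.0]))
    return float(np.trapezoid(y, x))


def _grid_step(rt: np.ndarray, i: int) -> float:
    if len(rt) > 1:
        return float(rt[1] - rt[0])
    return 0.1


def integrate_peak(trace: PSCTrace, peak_or_start, rt_end: float | None = None) -> float:
    """Trapezoidal area (score·minutes) of the trace between two bounds.

    Accepts either a :class:`PSCPeak` or explicit ``(rt_start, rt_end)``
    bounds (inclusive fraction midpoints).  Zero-valued anchors one
    fraction interval outside each bound are added, so a single-well
    peak of height ``v`` at spacing ``dt`` has area ``v * dt``.
    """
    if rt_end is None:
        rt_start, rt_end = peak_or_start.rt_start, peak_or_start.rt_end
    else:
        rt_start = float(peak_or_start)
    rt, values = trace.as_arrays()
    inside = np.flatnonzero((rt >= rt_start - 1e-12) & (rt <= rt_end + 1e-12))
    if inside.size == 0:
        raise ValueError("peak bounds contain no grid points")
    return _trapezoid_area(rt, values, int(inside[0]), int(inside[-1]))


def summed_score(table: pd.DataFrame, accession: str) -> float:
    """Sum of a protein's scores over all wells (0 if absent)."""
    sub = table[table["accession"] == accession]
    return float(sub["score"].sum()) if len(sub) else 0.0


def classify_family(
    description: str,
    accession: str = "",
    rules: list[tuple[str, str]] | None = None,
) -> str:
    """Toxin family from a protein description via ordered keyword rules.

    The description and accession are searched case-insensitively
    against each rule in order; the first hit wins and unmatched
    entries fall through to ``"other"``.
    """
    text = f"{description} {accession}".lower()
    for pattern, family in rules or DEFAULT_FAMILY_RULES:
        if re.search(pattern, text):
            return family
    return "other"


def family_abundance(
    quantities: dict[str, float],
    families: dict[str, str],
) -> list[FamilyQuant]:
    """Aggregate per-accession quantities into per-family fractions.

    *quantities* maps accession -> quantity (peak area or summed
    score); *families* maps accession -> family label (missing
    accessions fall back to "other").  Fractions sum to 1 whenever the
    grand total is positive; an all-zero input yields an empty list
    with a warning.  Families are ordered by descending total.
    """
    totals: dict[str, float] = {}
    for acc, q in quantities.items():
        fam = families.get(acc, "other")
        totals[fam] = totals.get(fam, 0.0) + float(q)
    grand = sum(totals.values())
    if grand <= 0:
        logger.warning("all family quantities are zero; nothing to normalize")
        return []
    out = [
        FamilyQuant(family=f, total=t, fraction=t / grand)
        for f, t in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return out


def match_uv_peaks(
    psc_peaks: list[PSCPeak],
    uv_rt: np.ndarray,
    uv_intensity: np.ndarray,
    rt_tolerance_min: float = 0.1,
    bound_frac: float = 0.05,
) -> list[UVMatch]:
    """Match PSC peaks to UV absorbance peaks by apex retention time.

    UV peaks are local maxima of the (finer-grid) UV trace; each peak's
    integration bounds extend outward from the apex to the first local
    minimum below ``bound_frac`` of the apex height.  A PSC peak is
    matched to the UV apex nearest its own apex when within
    ``rt_tolerance_min``; a UV peak claimed by more than one PSC peak
    marks all its claimants ambiguous (co-elution).  An empty UV trace
    leaves every PSC peak unmatched.
    """
    uv_rt = np.asarray(uv_rt, float)
    uv_intensity = np.asarray(uv_intensity, float)
    if uv_rt.size < 3 or not psc_peaks:
        return [
            UVMatch(p.accession, p.apex_rt, None, None, "unmatched") for p in psc_peaks
        ]
    prominence = 0.02 * float(uv_intensity.max()) if uv_intensity.max() > 0 else None
    apexes, _ = find_peaks(uv_intensity, prominence=prominence)
    claims: dict[int, list[int]] = {}
    chosen: list[int | None] = []
    for pi, peak in enumerate(psc_peaks):
        if apexes.size == 0:
            chosen.append(None)
            continue
        deltas = np.abs(uv_rt[apexes] - peak.apex_rt)
        best = int(np.argmin(deltas))
        if deltas[best] <= rt_tolerance_min:
            chosen.append(int(apexes[best]))
            claims.setdefault(int(apexes[best]), []).append(pi)
        else:
            chosen.append(None)
    matches = []
    for pi, (peak, apex_idx) in enumerate(zip(psc_peaks, chosen)):
        if apex_idx is None:
            matches.append(UVMatch(peak.accession, peak.apex_rt, None, None, "unmatched"))
            continue
        status = "ambiguous" if len(claims[apex_idx]) > 1 else "matched"
        lo, hi = _uv_bounds(uv_intensity, apex_idx, bound_frac)
        area = float(np.trapezoid(uv_intensity[lo : hi + 1], uv_rt[lo : hi + 1]))
        matches.append(
            UVMatch(peak.accession, peak.apex_rt, float(uv_rt[apex_idx]), area, status)
        )
    return matches


def _uv_bounds(intensity: np.ndarray, apex: int, bound_frac: float) -> tuple[int, int]:
    cutoff = bound_frac * intensity[apex]
    lo = apex
    while lo > 0 and intensity[lo - 1] <= intensity[lo] and intensity[lo] > cutoff:
        lo -= 1
    hi = apex
    n = len(intensity)
    while hi < n - 1 and intensity[hi + 1] <= intensity[hi] and intensity[hi] > cutoff:
        hi += 1
    return lo, hi


def peaks_frame(peaks: list[PSCPeak], families: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabular peak export with an optional family column."""
    records = []
    for p in peaks:
        rec = {
            "accession": p.accession,
            "rt_start": p.rt_start,
            "rt_end": p.rt_end,
            "apex_rt": p.apex_rt,
            "apex_value": p.apex_value,
            "area": p.area,
            "n_fractions": p.n_fractions,
        }
        if families is not None:
            rec["family"] = families.get(p.accession, "other")
        records.append(rec)
    cols = ["accession", "rt_start", "rt_end", "apex_rt", "apex_value", "area", "n_fractions"]
    if families is not None:
        cols.append("family")
    return pd.DataFrame.from_records(records, columns=cols)


def family_frame(quants: list[FamilyQuant]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [{"family": q.family, "total": q.total, "fraction": q.fraction} for q in quants],
        columns=["family", "total", "fraction"],
    )


def plot_family_pie(quants: list[FamilyQuant], path=None, title: str = ""):
    """Pie chart of relative family composition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if quants:
        ax.pie(
            [q.fraction for q in quants],
            labels=[q.family for q in quants],
            autopct="%1.1f%%",
            startangle=90,
        )
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
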