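"""Synthetic venom generator closing the loop for end-to-end tests.

Emulates the data a nanofractionation-proteomics run produces, with
full ground truth: each toxin elutes as a Gaussian of known apex and
width, the effluent is cut into fraction windows, and the amount
deposited in each well is the Gaussian probability mass of that window
times the toxin's abundance.  The search-engine response is modelled
as linear in digested amount with multiplicative lognormal noise —
the weakest assumption under which peak-area semiquantitation is
meaningful — and a detection floor below which a well reports no hit.
In parallel, each toxin contributes a scaled Gaussian XIC labelled
with its intact mass, and the UV trace is the abundance-weighted sum
of all toxin Gaussians.

Everything is reproducible: the same spec and seed give byte-identical
export files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .platemap import FractionSchedule, PlateLayout, rt_grid, run_well_ids
from .search_io import CANONICAL_COLUMNS, SearchHit

__all__ = [
    "SyntheticToxin",
    "SyntheticVenomSpec",
    "SimulationResult",
    "fraction_amounts",
    "simulate_venom",
    "default_venom_spec",
    "twin_peak_spec",
]


@dataclass(frozen=True)
class SyntheticToxin:
    """Ground truth for one simulated toxin.

    ``score_per_unit`` converts digested amount (arbitrary units) to a
    search score; ``detection_floor`` is the score below which a well
    reports no hit for this toxin.  ``apex_rt_min`` may be a tuple for
    multi-form toxins (isoform/PTM scenarios): each apex elutes an
    equal share of the abundance, and ``intact_mass_da`` may then also
    be a tuple giving each form its own mass.
    """

    accession: str
    description: str
    family: str
    apex_rt_min: float | tuple[float, ...]
    sigma_min: float
    abundance: float
    intact_mass_da: float | tuple[float, ...]
    score_per_unit: float = 1000.0
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be positive")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if self.score_per_unit <= 0:
            raise ValueError("score_per_unit must be positive")

    @property
    def apexes(self) -> tuple[float, ...]:
        a = self.apex_rt_min
        return a if isinstance(a, tuple) else (a,)

    @property
    def masses(self) -> tuple[float, ...]:
        m = self.intact_mass_da
        if isinstance(m, tuple):
            return m
        return tuple(m for _ in self.apexes)


@dataclass(frozen=True)
class SyntheticVenomSpec:
    """A full simulated venom: toxins plus acquisition parameters."""

    toxins: tuple[SyntheticToxin, ...]
    schedule: FractionSchedule = FractionSchedule()
    layout: PlateLayout = PlateLayout()
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        accs = [t.accession for t in self.toxins]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in synthetic spec")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class SimulationResult:
    """In-memory outputs of :func:`simulate_venom`."""

    per_well_hits: dict[str, list[SearchHit]]
    xic_frame: pd.DataFrame       # label, rt_min, intensity (long)
    uv_frame: pd.DataFrame        # rt_min, absorbance
    ground_truth: pd.DataFrame    # per form: accession, family, apex, window, ...
    job_map: pd.DataFrame         # job_id, well_id


def fraction_amounts(toxin: SyntheticToxin, schedule: FractionSchedule) -> np.ndarray:
    """Amount of toxin deposited per fraction of one run.

    Fraction *i* spans ``[(i-1)*dt, i*dt]``; its amount is the toxin's
    abundance times the Gaussian CDF mass of that window (split evenly
    across apexes for multi-form toxins), so totals conserve abundance
    up to window truncation.
    """
    n = schedule.wells_per_run
    dt = schedule.resolution_s / 60.0
    start = schedule.collection_start_min
    edges = start + dt * np.arange(n + 1)
    amounts = np.zeros(n)
    apexes = toxin.apexes
    share = toxin.abundance / len(apexes)
    for apex in apexes:
        cdf = norm.cdf(edges, loc=apex, scale=toxin.sigma_min)
        amounts += share * np.diff(cdf)
    return amounts


def simulate_venom(
    spec: SyntheticVenomSpec,
    out_dir: str | Path | None = None,
    xic_step_min: float = 0.01,
) -> SimulationResult:
    """Simulate one venom run; optionally write all exports to disk.

    Per well ``score = score_per_unit * amount * lognormal(cv)``; a hit
    is reported only when the score reaches the toxin's detection
    floor.  When *out_dir* is given, writes per-job export CSVs, a
    ``job_map.csv``, ``xic.csv``, ``uv.csv`` and ``ground_truth.csv``
    in exactly the formats the ingestion and correlation modules read.
    """
    rng = np.random.default_rng(spec.seed)
    schedule, layout = spec.schedule, spec.layout
    wells = run_well_ids(layout, schedule, run_index=1)
    n = schedule.wells_per_run
    grid = np.asarray(rt_grid(schedule))

    # lognormal with unit mean and the requested cv
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
        mu = -0.5 * sigma**2
    per_well: dict[str, list[SearchHit]] = {w: [] for w in wells}
    truth_rows = []
    for toxin in spec.toxins:
        amounts = fraction_amounts(toxin, schedule)
        noise = (
            rng.lognormal(mean=mu, sigma=sigma, size=n)
            if spec.noise_cv > 0
            else np.ones(n)
        )
        scores = toxin.score_per_unit * amounts * noise
        for i, w in enumerate(wells):
            s = float(scores[i])
            if s >= toxin.detection_floor and s > 0:
                per_well[w].append(
                    SearchHit(
                        well_id=w,
                        accession=toxin.accession,
                        protein_score=round(s, 4),
                        sequence_coverage=round(
                            min(100.0, 100.0 * amounts[i] / max(amounts.max(), 1e-12)), 2
                        ),
                        protein_mass=toxin.masses[0],
                        description=toxin.description,
                        species="Synthetica venomosa",
                        peptides=(),
                    )
                )
        for apex, mass in zip(toxin.apexes, toxin.masses):
            truth_rows.append(
                {
                    "accession": toxin.accession,
                    "family": toxin.family,
                    "abundance": toxin.abundance / len(toxin.apexes),
                    "apex_rt_min": apex,
                    "sigma_min": toxin.sigma_min,
                    "intact_mass_da": mass,
                    "window_start_min": apex - 3 * toxin.sigma_min,
                    "window_end_min": apex + 3 * toxin.sigma_min,
                }
            )
    truth = pd.DataFrame(truth_rows)
    total_ab = truth["abundance"].sum()
    truth["abundance_fraction"] = truth["abundance"] / total_ab if total_ab > 0 else 0.0

    # parallel intact-protein traces on a fine grid
    fine = np.arange(grid[0], grid[-1] + xic_step_min / 2, xic_step_min)
    xic_parts = []
    uv = np.zeros_like(fine)
    for toxin in spec.toxins:
        share = toxin.abundance / len(toxin.apexes)
        for apex, mass in zip(toxin.apexes, toxin.masses):
            profile = share * norm.pdf(fine, loc=apex, scale=toxin.sigma_min)
            uv += profile
            xic_parts.append(
                pd.DataFrame(
                    {"label": f"{mass:.1f}", "rt_min": np.round(fine, 6),
                     "intensity": profile}
                )
            )
    if xic_parts:
        xic_frame = (
            pd.concat(xic_parts, ignore_index=True)
            .groupby(["label", "rt_min"], as_index=False, sort=True)["intensity"]
            .sum()  # forms sharing one intact mass contribute to one XIC
            [["label", "rt_min", "intensity"]]
        )
    else:
        xic_frame = pd.DataFrame(columns=["label", "rt_min", "intensity"])
    uv_frame = pd.DataFrame(
        {"rt_min": np.round(fine, 6), "absorbance": uv}
    )

    job_map = pd.DataFrame(
        {"job_id": [f"job{i + 1:04d}" for i in range(n)], "well_id": wells}
    )
    result = SimulationResult(
        per_well_hits=per_well,
        xic_frame=xic_frame,
        uv_frame=uv_frame,
        ground_truth=truth,
        job_map=job_map,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SimulationResult, out_dir: Path) -> None:
    exports = out_dir / "exports"
    exports.mkdir(parents=True, exist_ok=True)
    for job, well in zip(result.job_map["job_id"], result.job_map["well_id"]):
        rows = []
        for hit in result.per_well_hits.get(well, []):
            rows.append(
                {
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
        pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(
            exports / f"{job}.csv", index=False, encoding="utf-8"
        )
    result.job_map.to_csv(out_dir / "job_map.csv", index=False, encoding="utf-8")
    result.xic_frame.to_csv(out_dir / "xic.csv", index=False, encoding="utf-8")
    result.uv_frame.to_csv(out_dir / "uv.csv", index=False, encoding="utf-8")
    result.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# canned scenarios

_DEFAULT_TOXINS = [
    # (accession, description, family, apex_min, sigma_min, abundance, mass_da)
    ("SVMP01", "Zinc metalloproteinase kistomin-like", "SVMP", 22.0, 0.30, 30.0, 46210.7),
    ("SVMP02", "Zinc metalloproteinase/disintegrin", "SVMP", 25.5, 0.35, 18.0, 47980.2),
    ("SVMP03", "Snake venom metalloproteinase P-II", "SVMP", 28.0, 0.30, 8.0, 30550.9),
    ("PLA201", "Acidic phospholipase A2", "PLA2", 12.0, 0.20, 22.0, 13958.3),
    ("PLA202", "Basic phospholipase A2 homolog", "PLA2", 14.0, 0.22, 12.0, 13781.6),
    ("PLA203", "Phospholipase A2 isoform 3", "PLA2", 16.5, 0.20, 5.0, 14102.4),
    ("SVSP01", "Thrombin-like serine protease", "SVSP", 18.5, 0.25, 15.0, 26120.8),
    ("SVSP02", "Snake venom serine proteinase 2", "SVSP", 20.5, 0.25, 9.0, 27433.1),
    ("SVSP03", "Serine protease ancrod-like", "SVSP", 31.0, 0.28, 4.0, 25990.4),
    ("TFTX01", "Alpha-neurotoxin, three-finger toxin", "3FTx", 6.0, 0.18, 14.0, 7821.5),
    ("TFTX02", "Cytotoxin 3, three-finger toxin", "3FTx", 8.0, 0.18, 7.0, 6712.9),
    ("TFTX03", "Weak three-finger toxin", "3FTx", 10.0, 0.18, 3.0, 7231.2),
]


def default_venom_spec(
    seed: int = 0,
    noise_cv: float = 0.2,
    floor_frac: float = 0.01,
    schedule: FractionSchedule | None = None,
) -> SyntheticVenomSpec:
    """Canonical 12-toxin, 4-family venom at the routine 6 s resolution.

    Toxin apexes are spread over the gradient window, widths are a few
    fraction widths, and family abundances are deliberately unequal.
    ``floor_frac`` sets each toxin's detection floor to that fraction
    of its expected apex score (default 1%), emulating wells where a
    trace amount falls below the search engine's reporting threshold.
    """
    schedule = schedule or FractionSchedule(resolution_s=6.0)
    toxins = []
    for acc, desc, fam, apex, sigma, ab, mass in _DEFAULT_TOXINS:
        toxin = SyntheticToxin(
            accession=acc,
            description=desc,
            family=fam,
            apex_rt_min=apex,
            sigma_min=sigma,
            abundance=ab,
            intact_mass_da=mass,
        )
        apex_score = toxin.score_per_unit * fraction_amounts(toxin, schedule).max()
        toxins.append(replace(toxin, detection_floor=floor_frac * apex_score))
    return SyntheticVenomSpec(
        toxins=tuple(toxins), schedule=schedule, noise_cv=noise_cv, seed=seed
    )


def twin_peak_spec(
    distinct_masses: bool = True,
    seed: int = 0,
    schedule: FractionSchedule | None = None,
) -> SyntheticVenomSpec:
    """One accession eluting as two peaks, for proteoform annotation.

    With ``distinct_masses`` the two elution forms carry different
    intact masses (a PTM/isoform scenario); otherwise both peaks share
    one mass (the conserved-peptide artifact scenario).
    """
    schedule = schedule or FractionSchedule(resolution_s=6.0)
    masses = (13958.3, 14000.1) if distinct_masses else (13958.3, 13958.3)
    toxin = SyntheticToxin(
        accession="PLA2X1",
        description="Phospholipase A2, glycosylated forms",
        family="PLA2",
        apex_rt_min=(12.0, 15.0),
        sigma_min=0.2,
        abundance=20.0,
        intact_mass_da=masses,
    )
    return SyntheticVenomSpec(
        toxins=(toxin,), schedule=schedule, noise_cv=0.0, seed=seed
    )
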