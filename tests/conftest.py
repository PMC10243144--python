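import io

import pandas as pd
import pytest

from venompsc.platemap import FractionSchedule, PlateLayout
from venompsc.search_io import SearchHit, merge_wells
from venompsc.synthetic import default_venom_spec, simulate_venom


@pytest.fixture(scope="session")
def layout():
    return PlateLayout()


@pytest.fixture(scope="session")
def schedule_6s():
    return FractionSchedule(resolution_s=6.0)


@pytest.fixture(scope="session")
def schedule_12s():
    return FractionSchedule(resolution_s=12.0)


def make_hit(well, accession, score, coverage=10.0, description=""):
    return SearchHit(
        well_id=well,
        accession=accession,
        protein_score=score,
        sequence_coverage=coverage,
        description=description,
    )


@pytest.fixture
def small_merged(layout, schedule_6s):
    """Three accessions spread over the first few fractions of a run."""
    hits = {
        "A1": [make_hit("A1", "TOX1", 100.0, description="Phospholipase A2")],
        "B1": [
            make_hit("B1", "TOX1", 300.0, description="Phospholipase A2"),
            make_hit("B1", "TOX2", 50.0, description="Zinc metalloproteinase"),
        ],
        "C1": [make_hit("C1", "TOX1", 150.0, description="Phospholipase A2")],
        "E1": [make_hit("E1", "TOX3", 80.0, description="Thrombin-like serine protease")],
    }
    return merge_wells(hits, schedule_6s, layout)


@pytest.fixture(scope="session")
def default_sim():
    """The canonical 12-toxin simulated venom, shared across tests."""
    spec = default_venom_spec(seed=11)
    return spec, simulate_venom(spec)


def export_csv(rows):
    """Build an in-memory per-well export stream from (acc, score, ...) dicts."""
    df = pd.DataFrame(rows)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf
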