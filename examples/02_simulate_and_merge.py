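"""Simulate a venom and merge its per-well search exports.

Generates the canonical 12-toxin synthetic venom (Gaussian elution,
lognormal score noise, 1% detection floor), writes per-well export
CSVs plus the job->well map, then ingests them back through the same
reader used for real exports.
"""

import tempfile
from pathlib import Path

from venompsc import default_venom_spec, merge_wells, simulate_venom
from venompsc.search_io import read_export_dir, read_job_well_map

with tempfile.TemporaryDirectory() as tmp:
    spec = default_venom_spec(seed=11)
    simulate_venom(spec, out_dir=tmp)

    job_map = read_job_well_map(Path(tmp) / "job_map.csv", spec.layout)
    per_well = read_export_dir(Path(tmp) / "exports", job_map)
    merged = merge_wells(per_well, spec.schedule, spec.layout)

print(f"{len(job_map)} wells searched, "
      f"{sum(1 for h in per_well.values() if h)} wells with hits")
print(f"merged table: {len(merged)} rows, "
      f"{merged['accession'].nunique()} accessions")
print(merged[["rt_min", "well_id", "accession", "score"]].head(5).to_string(index=False))
# Each row is one protein hit in one well; rt_min is the well's
# fractionation time, so sorting by it reconstructs elution order.
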