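"""One call from inputs to the full report bundle.

Runs every stage on the synthetic venom and prints the report counts.
The same RunConfig accepts real per-well exports via exports_dir and
job_map instead of synthetic=True.
"""

import json
import tempfile

from venompsc import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(out_dir=tmp, synthetic=True, seed=11)
    report = run_pipeline(config)

print(json.dumps(report["counts"], indent=2))
print("family fractions (area mode):")
for fam, frac in report["family_fractions"]["area"].items():
    print(f"  {fam:6s} {frac:.3f}")
# The bundle also contains merged.csv, traces, peaks.csv, the family
# pie chart, XIC matches and proteoform annotations; every number in
# report.json is recomputable from those CSVs.
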