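"""Flagging PTM/isoform candidates from PSC-XIC mass correlation.

One accession eluting as two PSC peaks is ambiguous: two proteoforms,
or one protein whose conserved peptides also matched a homologue?
Matching each peak to the intact-mass XICs decides: distinct masses
under the two peaks -> PTM/isoform candidate with the mass delta;
one shared mass -> shared-peptide artifact.
"""

from venompsc import (
    XICTrace,
    annotate_isoforms,
    build_psc,
    detect_peaks,
    match_psc_xic,
    merge_wells,
    simulate_venom,
    twin_peak_spec,
)

for distinct in (True, False):
    spec = twin_peak_spec(distinct_masses=distinct)
    sim = simulate_venom(spec)
    merged = merge_wells(sim.per_well_hits, spec.schedule, spec.layout)
    acc = spec.toxins[0].accession
    trace = build_psc(merged, acc, spec.schedule)
    peaks = detect_peaks(trace)
    xics = [
        XICTrace(label=str(l), rt_min=tuple(s["rt_min"]),
                 intensity=tuple(s["intensity"]))
        for l, s in sim.xic_frame.groupby("label")
    ]
    matches = match_psc_xic(peaks, {acc: trace}, xics,
                            rt_tolerance_min=0.1, min_similarity=0.7)
    ann = annotate_isoforms(acc, peaks, matches)
    label = "distinct masses" if distinct else "shared mass"
    print(f"{label}: {ann.n_peaks} peaks -> {ann.verdict}, "
          f"deltas {ann.mass_deltas_da} Da")
# A 41.8 Da delta between the matched masses is what a modification of
# that size would produce; equal masses mean the second peak is likely
# a homologue sharing conserved tryptic peptides.
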