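# Methods

## Plate geometry and time reconstruction

Collection fills a 384-well plate column-major in serpentine order:
down column 1 (A1..P1), up column 2 (P2..A2), alternating. The start
corner and initial direction are conventions of this package (the
A1-down choice is the common reading order for these collectors) and
the layout object is the single authority for the well↔fraction
bijection, tested exhaustively at both resolutions.

A fraction's retention time is the **midpoint** of its collection
window, `t0 + (i − ½)·Δt`: against an underlying elution profile the
midpoint is an unbiased sample point, whereas start-of-window would
shift every apex late by half a fraction. `rt_convention="start"` is
available for comparison with tools using the other convention. The
default collection window is 2208 s, giving 368 wells at 6 s per
fraction and 184 at 12 s; the delay between injection and fraction 1
(`collection_start_min`) defaults to 0 and should be set to the
instrument's actual dead time when mapping real runs. A second 12 s
run on one plate continues the same serpentine order at plate
fraction 185, matching how injection sequences are driven.

## Merged table

One row per (well, accession), sorted by retention time. Duplicate
accessions within one well keep only the highest-scoring record:
search engines emit one record per protein per search, so duplicates
indicate a malformed export, and scores are not additive evidence.
Canonical serialization is UTF-8 CSV with `.` decimals; the
spreadsheet writer is a convenience export, never the source of
truth. No protein inference or homologue grouping is attempted — the
search engine's per-well protein list is taken as given.

## PSC construction

Traces are built on the full fraction grid with **zero fill** where
an accession was not found, so a PSC returns to baseline like a real
chromatogram and peak bounding is well defined. No smoothing or
interpolation is applied: each point is the raw score of one well.
Two identities are maintained exactly and tested: the total protein
chromatogram equals the pointwise sum of all per-accession PSCs, and
its grid total equals the merged table's score total.

## Peak definition and integration

Scores exist only once per fraction, so peaks are defined
combinatorially rather than by curve fitting:

* a peak is a maximal run of nonzero fractions, allowing up to
  `gap_tolerance` (default 1) consecutive interior zeros — a single
  dropout well (failed digestion or injection) should not cut a peak
  in two;
* a run containing two local maxima is split at the interior minimum
  when that minimum is below `split_ratio` (default 0.5) times the
  smaller maximum. A **zero-valued valley never triggers a split**:
  zero interior fractions are exactly the dropouts `gap_tolerance`
  absorbs, and letting the split rule re-divide them would make the
  gap tolerance unusable whenever `split_ratio > 0`. The valley
  fraction joins the left segment, keeping peaks disjoint.

Areas are trapezoidal in score·minutes with zero anchors one fraction
interval outside each bound. This treats wells as point samples of a
continuous elution profile: a single-well toxin gets the triangular
area `score · Δt` instead of zero, and every area matches an
independent brute-force trapezoid to ≤ 1e-9 relative (tested on
hundreds of random traces). Minutes, not fraction indices, are the
integration axis so 6 s and 12 s runs are directly comparable.

## Family classification and composition

Classification is description-driven through an ordered, editable
regex→family table seeded with the canonical venom families; order
matters ("Zinc metalloproteinase/disintegrin" is an SVMP because the
metalloproteinase rule precedes the disintegrin rule). Unmatched
descriptions fall to "other". Composition is reported as normalized
family fractions in two modes — PSC peak area (default) and summed
score — because the two agree when elution is well behaved and their
disagreement is itself diagnostic.

## XIC/UV correlation and proteoform calls

XICs arrive pre-extracted as (rt, intensity) series on their own
finer grid and are linearly interpolated onto the PSC fraction grid
(outside points → 0). Shape similarity is the Pearson correlation
over the peak window widened by one fraction; the threshold defaults
to 0.7 and the apex tolerance to 0.1 min — both are configuration,
and tests assert behavior only at clearly-inside / clearly-outside
settings since any sharp cut on a continuous similarity is a
judgment call. The XIC apex for a peak is the XIC's maximum within
the tolerance-widened window, ties broken toward the smaller time
delta. UV peak bounds run outward from the apex to the first local
minimum below 5% of apex height; a UV peak claimed by two PSC peaks
marks both matches ambiguous rather than guessing an assignment.

Proteoform verdicts per accession: one peak → `single_form`;
≥ 2 peaks with distinct matched masses (difference > 1 Da) →
`multiple_masses_candidate_PTM_or_isoform` with all pairwise deltas;
≥ 2 peaks sharing one mass → `shared_peptide_artifact_suspected`;
≥ 2 peaks without enough mass matches → `unresolved_multiple_peaks`,
an explicit "no evidence" state added so the absence of XIC coverage
is never silently reported as a single form. Mass deltas are
descriptive only; mapping a delta to a specific modification is left
to the user (a delta→modification table can be supplied).

## Synthetic venom generator

The simulator emulates the structure the analysis relies on: each
toxin elutes as a Gaussian (apex, σ in minutes), the amount in a
fraction is the Gaussian CDF mass of its time window (conserving
abundance to truncation), and the search score is **linear in
digested amount** with multiplicative lognormal noise (default
cv 0.2, unit mean) and a per-toxin detection floor (default scenario:
1% of the apex score). Linearity is the weakest response model under
which semiquantitation is meaningful; real score–amount curves
saturate, which is why the package claims semi-, not absolute,
quantitation. The default scenario is one 6 s / 368-well run of 12
toxins in 4 families (SVMP, PLA2, SVSP, 3FTx) with unequal
abundances, apexes spread over 6–31 min and σ of 2–4 fraction widths
— small enough to run in seconds, large enough that rank recovery
and family composition are non-trivial.

What the simulator does **not** model: chromatographic tailing,
co-eluting interferences, score saturation, peptide-level artifacts
(shared peptides are emulated only at the intact-mass level), charge
deconvolution errors, or carry-over between wells. Passing recovery
tests therefore demonstrates the pipeline's correctness under the
stated response model, not robustness to every pathology of real
search data.

## Numerical choices

Scores in simulated exports are rounded to 4 decimals (CSV
stability); comparisons near the detection floor account for this.
Exact (not approximate) equality is asserted where the math is exact:
conservation of total score, permutation invariance of merging,
byte-identical reruns under a fixed seed. Degenerate inputs are
defined, not rejected: empty wells parse to empty hit lists, an
absent accession yields an all-zero trace, an all-zero trace yields
no peaks, and all-zero quantities yield an empty (warned) composition
rather than a division by zero.

## Problem sizes

The test suite and the reproduction script use one simulated 368-well
run (12 toxins), 200 random traces for the integration oracle, and
exhaustive enumeration (736 wells) for the mapping round trip —
sizes chosen to keep the full suite under ten seconds while leaving
none of the checked properties trivially satisfiable.

## Known limitations

Scores are relative evidence, not concentrations: between-protein
comparisons inherit every bias of the search engine's scoring.
Families are inferred from free-text descriptions, so accessions with
uninformative descriptions land in "other". The UV matcher assumes a
baseline-resolved UV trace; heavily overlapping UV peaks are flagged
ambiguous rather than deconvolved. Only rectangular plates up to
26 rows are supported, and multi-plate venoms (one venom spanning
plates) are out of scope.
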