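"""Trace resampling, shape similarity, XIC matching and proteoform calls."""

import math

import numpy as np
import pytest

from venompsc.correlate import (
    XICTrace,
    annotate_isoforms,
    match_psc_xic,
    resample_to_grid,
    shape_similarity,
)
from venompsc.psc import PSCTrace
from venompsc.quant import detect_peaks


def gaussian_trace(apex, sigma=0.2, height=100.0, n=120, dt=0.1, accession="T"):
    rt = np.round(dt * (np.arange(n) + 0.5), 10)
    values = height * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
    values[values < 1e-3] = 0.0
    return PSCTrace(accession, "", tuple(rt), tuple(values))


def gaussian_xic(label, apex, sigma=0.2, height=1e5, start=0.0, end=12.0, step=0.01):
    rt = np.round(np.arange(start, end, step), 10)
    return XICTrace(
        label=label,
        rt_min=tuple(rt),
        intensity=tuple(height * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)),
    )


class TestResample:
    def test_identity_on_own_grid(self):
        rt = [0.0, 1.0, 2.0]
        assert list(resample_to_grid(rt, [5.0, 7.0, 9.0], rt)) == [5.0, 7.0, 9.0]

    def test_midpoint_is_linear(self):
        assert resample_to_grid([0.0, 1.0], [0.0, 100.0], [0.5])[0] == 50.0

    def test_outside_range_maps_to_zero(self):
        out = resample_to_grid([1.0, 2.0], [10.0, 10.0], [0.0, 3.0])
        assert list(out) == [0.0, 0.0]

    def test_degenerate_trace_rejected(self):
        with pytest.raises(ValueError):
            resample_to_grid([1.0], [2.0], [1.0])


class TestShapeSimilarity:
    def test_identical_windows_give_one(self):
        w = [0.0, 1.0, 4.0, 1.0, 0.0]
        assert shape_similarity(w, w) == pytest.approx(1.0)

    def test_affine_transform_gives_one(self):
        w = np.array([0.0, 1.0, 4.0, 1.0, 0.0])
        assert shape_similarity(w, 3.0 * w + 7.0) == pytest.approx(1.0)

    def test_negated_window_gives_minus_one(self):
        w = np.array([0.0, 1.0, 4.0, 1.0, 0.0])
        assert shape_similarity(w, -w) == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(30), rng.random(30)
        assert shape_similarity(a, b) == pytest.approx(shape_similarity(b, a))

    def test_zero_variance_is_undefined(self):
        assert math.isnan(shape_similarity([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]))

    def test_gaussian_shifted_three_sigma_dissimilar(self):
        sigma = 0.2
        grid = np.arange(0.0, 4.0, 0.05)
        a = np.exp(-0.5 * ((grid - 2.0) / sigma) ** 2)
        b = np.exp(-0.5 * ((grid - 2.0 - 3 * sigma) / sigma) ** 2)
        window = (grid > 1.4) & (grid < 2.6)
        assert shape_similarity(a[window], b[window]) < 0.5


class TestMatchPscXic:
    def setup_method(self):
        self.trace = gaussian_trace(6.0)
        self.peaks = detect_peaks(self.trace)
        self.traces = {"T": self.trace}

    def test_nearby_apex_with_similar_shape_matches(self):
        xic = gaussian_xic("14000.0", 6.03)
        matches = match_psc_xic(self.peaks, self.traces, [xic], 0.1, 0.7)
        assert len(matches) == 1
        assert abs(matches[0].rt_delta_min) <= 0.1
        assert matches[0].shape_similarity >= 0.7

    def test_distant_apex_does_not_match(self):
        xic = gaussian_xic("14000.0", 8.0)
        assert match_psc_xic(self.peaks, self.traces, [xic], 0.1, 0.7) == []

    def test_two_candidates_ranked_by_similarity(self):
        good = gaussian_xic("14000.0", 6.0, sigma=0.2)
        worse = gaussian_xic("15000.0", 6.05, sigma=0.45)
        matches = match_psc_xic(self.peaks, self.traces, [worse, good], 0.1, 0.3)
        assert [m.xic_label for m in matches] == ["14000.0", "15000.0"]
        assert matches[0].shape_similarity >= matches[1].shape_similarity

    def test_matching_stable_under_trace_reordering(self):
        xics = [gaussian_xic("14000.0", 6.0), gaussian_xic("15000.0", 6.04)]
        m1 = match_psc_xic(self.peaks, self.traces, xics, 0.1, 0.3)
        m2 = match_psc_xic(self.peaks, self.traces, xics[::-1], 0.1, 0.3)
        assert [(m.xic_label, m.rt_delta_min) for m in m1] == [
            (m.xic_label, m.rt_delta_min) for m in m2
        ]


class TestAnnotateIsoforms:
    def two_peak_setup(self, masses):
        rt = np.round(0.1 * (np.arange(120) + 0.5), 10)
        values = 100.0 * (
            np.exp(-0.5 * ((rt - 4.0) / 0.2) ** 2)
            + np.exp(-0.5 * ((rt - 8.0) / 0.2) ** 2)
        )
        values[values < 1e-3] = 0.0
        trace = PSCTrace("ACC", "", tuple(rt), tuple(values))
        peaks = detect_peaks(trace)
        assert len(peaks) == 2
        xics = [
            gaussian_xic(f"{m:.1f}", apex)
            for m, apex in zip(masses, (4.0, 8.0))
        ]
        matches = match_psc_xic(peaks, {"ACC": trace}, xics, 0.1, 0.7)
        return peaks, matches

    def test_distinct_masses_flag_ptm_or_isoform(self):
        peaks, matches = self.two_peak_setup([13958.3, 14000.1])
        ann = annotate_isoforms("ACC", peaks, matches)
        assert ann.verdict == "multiple_masses_candidate_PTM_or_isoform"
        assert ann.mass_deltas_da == (41.8,)

    def test_shared_mass_flags_conserved_peptide_artifact(self):
        peaks, matches = self.two_peak_setup([13958.3, 13958.3])
        ann = annotate_isoforms("ACC", peaks, matches)
        assert ann.verdict == "shared_peptide_artifact_suspected"
        assert ann.mass_deltas_da == ()

    def test_single_peak_single_form(self):
        trace = gaussian_trace(6.0, accession="ACC")
        peaks = detect_peaks(trace)
        xic = gaussian_xic("13958.3", 6.0)
        matches = match_psc_xic(peaks, {"ACC": trace}, [xic], 0.1, 0.7)
        ann = annotate_isoforms("ACC", peaks, matches)
        assert ann.verdict == "single_form"

    def test_two_peaks_without_masses_unresolved(self):
        peaks, _ = self.two_peak_setup([13958.3, 14000.1])
        ann = annotate_isoforms("ACC", peaks, [])
        assert ann.verdict == "unresolved_multiple_peaks"
        assert ann.mass_deltas_da == ()
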