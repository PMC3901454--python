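"""Gap-tolerant consecutive-probe peak calling against a brute-force
interval oracle, plus positivity flagging and footprint scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirachip.peaks import (
    call_peaks,
    flag_positive_probes,
    score_peak_in_sample,
)
from tests.conftest import brute_force_peaks, build_design, normalized_sample


def as_spans(peaks):
    return [(p.region_id, p.probe_indices[0], p.probe_indices[-1]) for p in peaks]


def flags_from_string(s):
    return np.array([c == "P" for c in s])


def test_positivity_is_strictly_above_threshold():
    s = normalized_sample([1.01, 1.0, 0.99])
    assert flag_positive_probes(s).tolist() == [True, False, False]
    assert flag_positive_probes(normalized_sample([0.0, 0.0])).tolist() == [False, False]
    assert flag_positive_probes(normalized_sample([-1.0, 1.0]), threshold=0.0).tolist() == [False, True]


def test_positivity_refuses_unnormalized_samples():
    s = normalized_sample([1.5, 2.0])
    s.normalized = False
    with pytest.raises(ValueError, match="not normalized"):
        flag_positive_probes(s)


@pytest.mark.parametrize(
    "pattern,expected",
    [
        ("PPPP", [("r0", 0, 3)]),  # minimum four consecutive positives
        ("PPNPP", [("r0", 0, 4)]),  # one gap tolerated
        ("PPNPNPP", []),  # any single-gap window holds <= 3 positives
        ("NNNN", []),
        ("PPPNP", [("r0", 0, 4)]),  # 4 positives across one gap
        ("NPPPPN", [("r0", 1, 4)]),  # boundaries must be positive
        ("PPNNPP", []),  # a two-probe gap always breaks the run
    ],
)
def test_peak_rule_examples(pattern, expected):
    design = build_design([len(pattern)])
    flags = flags_from_string(pattern)
    peaks = call_peaks(design, flags)
    assert as_spans(peaks) == expected
    assert as_spans(peaks) == [
        (r, a, b) for r, a, b in brute_force_peaks(design, flags)
    ]


def test_gap_probe_counts_in_mean_but_not_in_positives():
    design = build_design([5])
    ratios = np.array([2.0, 2.0, 0.0, 2.0, 2.0])
    peaks = call_peaks(design, ratios > 1.0, ratios)
    assert len(peaks) == 1
    p = peaks[0]
    assert p.n_positive == 4 and p.n_gaps == 1
    assert p.mean_log2_ratio == pytest.approx(8.0 / 5.0)
    assert p.start == design.probes[0].start and p.end == design.probes[4].end


def test_peaks_do_not_cross_regions():
    design = build_design([4, 4])
    flags = np.ones(8, bool)
    peaks = call_peaks(design, flags)
    assert as_spans(peaks) == [("r0", 0, 3), ("r1", 4, 7)]


def test_large_probe_spacing_breaks_runs():
    starts = [[1000, 1100, 1200, 2000, 2100, 2200, 2300]]  # 750 bp gap inside
    design = build_design([7], starts_per_region=starts)
    flags = np.ones(7, bool)
    peaks = call_peaks(design, flags, max_spacing=500)
    assert as_spans(peaks) == [("r0", 3, 6)]
    assert as_spans(peaks) == [(r, a, b) for r, a, b in brute_force_peaks(design, flags)]


def test_missed_start_inside_failed_window_is_still_found():
    # greedy from probe 0 spends the gap early and falls short; a valid
    # four-positive run starting later inside that window must be emitted
    pattern = "PNPPNPPP"
    design = build_design([len(pattern)])
    flags = flags_from_string(pattern)
    assert as_spans(call_peaks(design, flags)) == [
        (r, a, b) for r, a, b in brute_force_peaks(design, flags)
    ]


def test_oracle_equivalence_on_random_vectors():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        sizes = rng.integers(1, 15, size=rng.integers(1, 4)).tolist()
        design = build_design(sizes)
        flags = rng.random(design.n_probes) < rng.uniform(0.3, 0.9)
        got = as_spans(call_peaks(design, flags))
        want = [(r, a, b) for r, a, b in brute_force_peaks(design, flags)]
        assert got == want, f"sizes={sizes} flags={flags.astype(int)}"


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.lists(st.booleans(), min_size=1, max_size=30))
def test_oracle_equivalence_property(bits):
    design = build_design([len(bits)])
    flags = np.array(bits)
    got = as_spans(call_peaks(design, flags))
    want = [(r, a, b) for r, a, b in brute_force_peaks(design, flags)]
    assert got == want


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.booleans(), min_size=4, max_size=25), st.integers(4, 7))
def test_raising_min_positive_never_adds_peaks(bits, stricter):
    design = build_design([len(bits)])
    flags = np.array(bits)
    assert len(call_peaks(design, flags, min_positive=stricter)) <= len(
        call_peaks(design, flags, min_positive=4)
    )


def test_lowering_threshold_never_loses_positive_probes():
    rng = np.random.default_rng(1)
    s = normalized_sample(rng.normal(1.0, 0.5, 200))
    n_hi = flag_positive_probes(s, threshold=1.2).sum()
    n_lo = flag_positive_probes(s, threshold=0.8).sum()
    assert n_lo >= n_hi


def test_emitted_peaks_never_overlap():
    rng = np.random.default_rng(7)
    design = build_design([30])
    flags = rng.random(30) < 0.7
    peaks = call_peaks(design, flags)
    covered = set()
    for p in peaks:
        assert not covered.intersection(p.probe_indices)
        covered.update(p.probe_indices)


def test_flags_length_mismatch_rejected(small_design):
    with pytest.raises(ValueError, match="length"):
        call_peaks(small_design, np.ones(3, bool))


def test_score_peak_in_sample_means_and_errors():
    design = build_design([6])
    ratios = np.array([2.0, 2.0, 2.0, 2.0, 0.0, 0.0])
    peaks = call_peaks(design, ratios > 1.0, ratios)
    other = normalized_sample([1.0, 2.0, 3.0, 4.0, 0.0, 0.0], "other")
    assert score_peak_in_sample(peaks[0], other) == pytest.approx(2.5)
    constant = normalized_sample([2.0] * 6, "const")
    assert score_peak_in_sample(peaks[0], constant) == pytest.approx(2.0)

    rng = np.random.default_rng(9)
    vals = rng.normal(0, 1, 6)
    rnd = normalized_sample(vals, "rnd")
    manual = sum(vals[i] for i in peaks[0].probe_indices) / len(peaks[0].probe_indices)
    assert abs(score_peak_in_sample(peaks[0], rnd) - manual) < 1e-12

    short = normalized_sample([1.0, 2.0], "short")
    with pytest.raises(IndexError):
        score_peak_in_sample(peaks[0], short)
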