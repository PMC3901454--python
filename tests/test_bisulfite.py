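"""Bisulfite conversion, COBRA fragment arithmetic, clone calling
round-trips, QC, percentages, and lollipop rendering."""

import numpy as np
import pytest
from scipy import stats

from mirachip.bisulfite import (
    METHYLATED,
    MISSING,
    UNMETHYLATED,
    Amplicon,
    CloneAlignmentError,
    CloneCall,
    MethylationMatrix,
    align_and_call_clone,
    bisulfite_convert,
    clone_qc,
    cobra_site_analysis,
    percent_methylation,
    render_lollipop,
)
from mirachip.simulate import SimulationConfig, generate_amplicon, simulate_bisulfite_clones

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMP)[::-1]


def random_amplicon(rng, length=120):
    return generate_amplicon(f"amp{rng.integers(10**9)}", length=length,
                             n_cpgs=max(2, length // 20), seed=int(rng.integers(2**31)))


def test_conversion_retains_methylated_cpg_only():
    assert bisulfite_convert("ACGTCGT", {1}) == "ACGTTGT"
    assert bisulfite_convert("ATTGGA", set()) == "ATTGGA"  # no C at all
    assert bisulfite_convert("ACGACG", {1, 4}) == "ACGACG"


def test_conversion_rejects_non_cpg_methylation():
    with pytest.raises(ValueError, match="not CpG"):
        bisulfite_convert("ACGTCAT", {4})  # C at 4 is CA, not CG


def test_partial_conversion_matches_binomial_oracle():
    rng = np.random.default_rng(13)
    seq = "".join(rng.choice(list("ACT"), size=10_000))  # Cs never followed by G? enforce:
    seq = seq.replace("CG", "CT")
    n_c = seq.count("C")
    out = bisulfite_convert(seq, set(), conversion_rate=0.95, seed=99)
    converted = sum(1 for a, b in zip(seq, out) if a == "C" and b == "T")
    lo, hi = stats.binom.ppf([0.005, 0.995], n_c, 0.95)
    assert lo <= converted <= hi


def test_cobra_single_site_arithmetic():
    amp = Amplicon("a", "AATTCGATT")
    rep = cobra_site_analysis(amp)  # TaqI TCGA at index 3
    assert [s.position for s in rep.sites] == [3]
    assert [s.cpg_position for s in rep.sites] == [4]
    assert sum(rep.fragments_methylated) == 9
    assert rep.fragments_unmethylated == [9]
    # explicit state: methylated -> cleaved, unmethylated -> uncut
    assert cobra_site_analysis(amp, methylated_positions={4}).fragments_observed == [4, 5]
    assert cobra_site_analysis(amp, methylated_positions=set()).fragments_observed == [9]


def test_cobra_no_sites_is_uncut():
    amp = Amplicon("a", "AATTAATTGG")
    rep = cobra_site_analysis(amp)
    assert rep.verdict == "uncut"
    assert rep.fragments_methylated == [len(amp.sequence)]


def test_cobra_motif_must_contain_cpg():
    amp = Amplicon("a", "AATTCGATT")
    with pytest.raises(ValueError, match="CpG"):
        cobra_site_analysis(amp, enzyme_motif="GATC")


def test_cobra_fragments_sum_against_split_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        amp = generate_amplicon(f"a{rng.integers(10**6)}", length=500, n_cpgs=12,
                                seed=int(rng.integers(2**31)), n_taqai_sites=4)
        rep = cobra_site_analysis(amp, methylated_positions=set(amp.cpg_positions))
        n_sites = len(rep.sites)
        assert len(rep.fragments_observed) == n_sites + 1
        assert sum(rep.fragments_observed) == len(amp.sequence)
        # retained-site count equals methylated-CpG-in-motif count
        assert sum(1 for s in rep.sites if s.retained) == n_sites
        # independent oracle: split the string at the cut points
        cuts = sorted(s.position + 1 for s in rep.sites)  # T^CGA
        pieces = np.diff([0] + cuts + [len(amp.sequence)]).tolist()
        assert rep.fragments_observed == pieces


def test_clone_roundtrip_extremes():
    amp = generate_amplicon("amp", length=200, n_cpgs=8, seed=2)
    all_meth = bisulfite_convert(amp.sequence, set(amp.cpg_positions))
    call = align_and_call_clone(all_meth, amp)
    assert np.all(call.per_cpg == METHYLATED)
    assert call.conversion_efficiency == 1.0
    assert call.pass_qc

    none_meth = bisulfite_convert(amp.sequence, set())
    call = align_and_call_clone(none_meth, amp)
    assert np.all(call.per_cpg == UNMETHYLATED)


def test_clone_roundtrip_random_states_and_orientations():
    rng = np.random.default_rng(21)
    for _ in range(10):
        amp = random_amplicon(rng)
        states = rng.random(amp.n_cpgs) < 0.5
        meth = {p for p, s in zip(amp.cpg_positions, states) if s}
        read = bisulfite_convert(amp.sequence, meth)
        for oriented in (read, revcomp(read)):
            call = align_and_call_clone(oriented, amp)
            np.testing.assert_array_equal(call.per_cpg == METHYLATED, states)


def test_simulated_clone_calls_match_truth():
    amp = generate_amplicon("amp", length=300, n_cpgs=12, seed=7)
    cfg = SimulationConfig(conversion_rate=1.0, seed=8)
    clones, truth = simulate_bisulfite_clones(amp, [0.4] * amp.n_cpgs, 50, cfg)
    calls = np.vstack(
        [align_and_call_clone(seq, amp, clone_id=cid).per_cpg for cid, seq in clones]
    )
    np.testing.assert_array_equal(calls == METHYLATED, truth)


def test_unalignable_read_raises():
    amp = generate_amplicon("amp", length=120, n_cpgs=4, seed=3)
    garbage = "G" * 120
    with pytest.raises(CloneAlignmentError, match="amp"):
        align_and_call_clone(garbage, amp, clone_id="bad1")


def test_incomplete_conversion_lowers_efficiency_and_qc():
    amp = generate_amplicon("amp", length=300, n_cpgs=6, seed=4)
    read = bisulfite_convert(amp.sequence, set(), conversion_rate=0.5, seed=1)
    call = align_and_call_clone(read, amp)
    assert call.conversion_efficiency < 0.95
    assert clone_qc(call) is False
    assert clone_qc(call, min_conversion=0.0) is True
    perfect = align_and_call_clone(bisulfite_convert(amp.sequence, set()), amp)
    assert clone_qc(perfect) is True
    near = CloneCall("c", np.zeros(amp.n_cpgs, np.int8), 0.90, True)
    assert clone_qc(near) is False  # 0.90 < default 0.95


def test_percent_methylation_counting_oracle():
    amp = Amplicon("a", "ACGTACGTACGTACGTAACGA")
    assert amp.n_cpgs == 5
    rows = [
        [1, 1, 1, 0, 0],
        [1, 1, 0, 0, 0],
        [1, 0, 0, 0, -1],
    ]
    clones = [CloneCall(f"c{i}", np.array(r, np.int8), 1.0, True) for i, r in enumerate(rows)]
    matrix = MethylationMatrix(amp, clones)
    # 6 methylated / (6 + 8 unmethylated); the missing call is excluded
    assert percent_methylation(matrix) == pytest.approx(100 * 6 / 14)

    all_meth = MethylationMatrix(amp, [CloneCall("c", np.ones(5, np.int8), 1.0, True)])
    assert percent_methylation(all_meth) == 100.0


def test_percent_methylation_invariant_to_order_and_duplication():
    amp = Amplicon("a", "ACGTACGTT")
    clones = [
        CloneCall("c0", np.array([1, 0], np.int8), 1.0, True),
        CloneCall("c1", np.array([0, 0], np.int8), 1.0, True),
    ]
    m1 = MethylationMatrix(amp, clones)
    m2 = MethylationMatrix(amp, clones[::-1])
    m3 = MethylationMatrix(amp, clones + clones)
    assert percent_methylation(m1) == percent_methylation(m2) == percent_methylation(m3)


def test_percent_methylation_errors_without_callable_sites():
    amp = Amplicon("a", "ACGTT")
    empty = MethylationMatrix(amp, [])
    with pytest.raises(ValueError):
        percent_methylation(empty)
    all_missing = MethylationMatrix(amp, [CloneCall("c", np.array([MISSING], np.int8), 1.0, True)])
    with pytest.raises(ValueError, match="callable"):
        percent_methylation(all_missing, qc_only=False)


def test_lollipop_glyphs_and_percentage():
    amp = Amplicon("a", "ACGTACGTT")
    matrix = MethylationMatrix(
        amp, [CloneCall("c0", np.array([METHYLATED, UNMETHYLATED], np.int8), 1.0, True)]
    )
    text = render_lollipop(matrix)
    assert "●○" in text
    assert "50.0% methylated" in text

    empty = render_lollipop(MethylationMatrix(amp, []))
    assert "no clones" in empty


def test_lollipop_glyph_counts_equal_call_counts():
    rng = np.random.default_rng(2)
    amp = generate_amplicon("amp", length=200, n_cpgs=10, seed=5)
    clones = [
        CloneCall(f"c{i}", rng.integers(-1, 2, amp.n_cpgs).astype(np.int8), 1.0, True)
        for i in range(6)
    ]
    matrix = MethylationMatrix(amp, clones)
    text = render_lollipop(matrix)
    arr = matrix.to_array()
    assert text.count("●") == int((arr == METHYLATED).sum())
    assert text.count("○") == int((arr == UNMETHYLATED).sum())
    assert text.count("·") == int((arr == MISSING).sum())


def test_lollipop_figure_writes_image(tmp_path):
    amp = Amplicon("a", "ACGTACGTT")
    matrix = MethylationMatrix(
        amp, [CloneCall("c0", np.array([METHYLATED, UNMETHYLATED], np.int8), 1.0, True)]
    )
    from mirachip.bisulfite import render_lollipop_figure

    out = tmp_path / "lolli.png"
    render_lollipop_figure(matrix, out)
    assert out.stat().st_size > 0
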