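"""Synthetic-data generator: determinism, tiling arithmetic, injected
signal conservation, and the statistical structure of drawn quantities."""

import numpy as np
import pytest
from scipy import stats

from mirachip.simulate import (
    SHARED,
    SimulationConfig,
    generate_amplicon,
    generate_array_design,
    simulate_bisulfite_clones,
    simulate_sample_intensities,
    simulate_truth_methylome,
)


def test_design_is_deterministic_and_seed_sensitive():
    cfg = SimulationConfig(n_regions=10, probes_per_region=(8, 12), seed=7)
    d1, d2 = generate_array_design(cfg), generate_array_design(cfg)
    assert [p.probe_id for p in d1.probes] == [p.probe_id for p in d2.probes]
    assert [p.start for p in d1.probes] == [p.start for p in d2.probes]
    assert len(d1.regions) == 10
    assert 80 <= d1.n_probes <= 120
    d3 = generate_array_design(SimulationConfig(n_regions=10, probes_per_region=(8, 12), seed=8))
    assert [p.start for p in d3.probes] != [p.start for p in d1.probes]


def test_tiling_arithmetic_single_region():
    cfg = SimulationConfig(
        n_regions=1, probes_per_region=5, probe_spacing=100, probe_length=50,
        first_region_start=1000, seed=0,
    )
    d = generate_array_design(cfg)
    assert [p.start for p in d.probes] == [1000, 1100, 1200, 1300, 1400]
    assert all(p.end - p.start == 50 for p in d.probes)
    assert d.regions[0].kind == "cpg_island"


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_regions=0)
    with pytest.raises(ValueError):
        SimulationConfig(peak_density=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(conversion_rate=-0.1)


@pytest.mark.parametrize("density,expected", [(0.0, 0), (1.0, 20)])
def test_peak_density_extremes(density, expected):
    cfg = SimulationConfig(n_regions=20, peak_density=density, seed=3)
    d = generate_array_design(cfg)
    truth = simulate_truth_methylome(d, cfg)
    assert len(truth.peaks) == expected


def test_peak_count_matches_binomial_oracle():
    cfg = SimulationConfig(n_regions=1000, probes_per_region=(6, 8), peak_density=0.5, seed=11)
    d = generate_array_design(cfg)
    truth = simulate_truth_methylome(d, cfg)
    lo = stats.binom.ppf(0.005, 1000, 0.5)
    hi = stats.binom.ppf(0.995, 1000, 0.5)
    assert lo <= len(truth.peaks) <= hi


def test_truth_peaks_span_at_least_min_callable():
    cfg = SimulationConfig(n_regions=50, peak_density=1.0, seed=2)
    d = generate_array_design(cfg)
    truth = simulate_truth_methylome(d, cfg)
    for p in truth.peaks:
        n_region = len(d.region_probe_indices(p.region_id))
        assert p.n_probes >= min(cfg.min_peak_span, n_region)
        assert p.effect >= cfg.min_effect


def test_noise_free_signal_conservation():
    """With zero noise and zero dye bias the raw log2 ratio equals the
    injected effect exactly on every probe."""
    cfg = SimulationConfig(
        n_regions=10, peak_density=0.5, noise_sd=0.0, dye_bias=(0.0,), seed=4
    )
    d = generate_array_design(cfg)
    truth = simulate_truth_methylome(d, cfg)
    s = simulate_sample_intensities(d, truth, "treated", cfg, "T1")
    effect = np.zeros(d.n_probes)
    for p in truth.peaks_for_group("treated"):
        idx = d.region_probe_indices(p.region_id)
        a, b = p.probe_span
        effect[idx[a : b + 1]] += p.effect
    np.testing.assert_allclose(s.raw_log2_ratio(), effect, atol=1e-9)
    assert np.all(s.mira_raw > 0) and np.all(s.input_raw > 0)


def test_constant_dye_bias_is_additive():
    cfg = SimulationConfig(n_regions=5, peak_density=0.0, noise_sd=0.0, dye_bias=(0.5,), seed=4)
    d = generate_array_design(cfg)
    truth = simulate_truth_methylome(d, cfg)
    s = simulate_sample_intensities(d, truth, "control", cfg, "C1")
    np.testing.assert_allclose(s.raw_log2_ratio(), 0.5, atol=1e-9)


def test_off_peak_ratio_mean_obeys_clt_bound():
    cfg = SimulationConfig(
        n_regions=800, probes_per_region=(12, 14), peak_density=0.0,
        noise_sd=0.3, dye_bias=(0.5,), seed=9,
    )
    d = generate_array_design(cfg)
    truth = simulate_truth_methylome(d, cfg)
    s = simulate_sample_intensities(d, truth, "control", cfg, "C1")
    m = s.raw_log2_ratio()
    assert m.size >= 9000
    assert abs(m.mean() - 0.5) <= 3 * 0.3 / np.sqrt(m.size)


def test_differential_injection_split_and_groups():
    cfg = SimulationConfig(n_regions=60, peak_density=0.3, n_differential=8, seed=6)
    d = generate_array_design(cfg)
    truth = simulate_truth_methylome(d, cfg)
    assert len(truth.differential) == 8
    hyper = [p for p, dn in truth.differential if dn == "hyper"]
    hypo = [p for p, dn in truth.differential if dn == "hypo"]
    assert len(hyper) == 4 and len(hypo) == 4
    assert all(p.group == cfg.treated_group for p in hyper)
    assert all(p.group == cfg.control_group for p in hypo)
    # differential peaks live in regions without a shared peak
    shared_regions = {p.region_id for p in truth.peaks if p.group == SHARED}
    assert all(p.region_id not in shared_regions for p in hyper + hypo)


def test_clone_simulation_extremes_and_binomial_oracle():
    amp = generate_amplicon("amp", length=400, n_cpgs=38, seed=1)
    cfg = SimulationConfig(conversion_rate=1.0, seed=5)
    clones, truth = simulate_bisulfite_clones(amp, [1.0] * amp.n_cpgs, 5, cfg)
    for _cid, seq in clones:
        for p in amp.cpg_positions:
            assert seq[p] == "C"
        for i, base in enumerate(amp.sequence):
            if base == "C" and i not in amp.cpg_positions:
                assert seq[i] == "T"
    assert truth.all()

    clones, truth = simulate_bisulfite_clones(amp, [0.0] * amp.n_cpgs, 5, cfg)
    assert not truth.any()
    for _cid, seq in clones:
        assert all(seq[p] == "T" for p in amp.cpg_positions)

    _clones, truth = simulate_bisulfite_clones(amp, [0.29] * amp.n_cpgs, 50, cfg)
    n = truth.size
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.29)
    assert lo <= truth.sum() <= hi


def test_clone_simulation_validates_probabilities():
    amp = generate_amplicon("amp", length=200, n_cpgs=6, seed=1)
    cfg = SimulationConfig(seed=0)
    with pytest.raises(ValueError):
        simulate_bisulfite_clones(amp, [0.5] * (amp.n_cpgs - 1), 3, cfg)
    with pytest.raises(ValueError):
        simulate_bisulfite_clones(amp, [1.5] * amp.n_cpgs, 3, cfg)
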