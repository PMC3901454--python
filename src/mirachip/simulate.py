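"""Synthetic MIRA-chip experiments with known ground truth.

The generator emulates the structure the analysis pipeline assumes:
a NimbleGen-style tiling of CpG islands and promoters, MIRA-enrichment
peaks over methylated regions shared across replicate samples, an
intensity-dependent dye bias (so loess has a real target), injected
hyper-/hypomethylation differences between groups, and bisulfite clone
reads with per-CpG methylation states and imperfect conversion.

Model per probe (log2 scale):

    input  = baseline + N(0, baseline_sd)
    MIRA   = input + effect(probe) + dye_bias(A) + N(0, noise_sd)

where effect(probe) is the elevation of any truth peak covering the probe
in the sample's group, and dye_bias is a polynomial in the mean
log-intensity A = (MIRA + input)/2 evaluated before bias is added.
With noise_sd = 0 and zero dye bias the raw log2 ratio equals the injected
effect exactly on every probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._rng import substream
from .bisulfite import Amplicon, bisulfite_convert
from .design import ArraySample, Probe, ProbeDesign, Region

__all__ = [
    "SimulationConfig",
    "TruthPeak",
    "TruthSet",
    "generate_array_design",
    "simulate_truth_methylome",
    "simulate_sample_intensities",
    "simulate_bisulfite_clones",
    "generate_amplicon",
]

#: group label for peaks shared by every sample group
SHARED = "*"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic experiment.

    Defaults describe a compact but realistic array: regions of 8-15 probes
    tiled every 100 bp, ~30% of regions methylated, peak elevation ~2 log2
    units over a noise floor of 0.3, and a quadratic dye bias.
    """

    n_regions: int = 200
    probes_per_region: tuple[int, int] = (8, 15)
    probe_length: int = 50
    probe_spacing: int = 100  # start-to-start, bp
    first_region_start: int = 1000
    inter_region_gap: int = 10_000  # bp between consecutive regions
    n_chromosomes: int = 3
    peak_density: float = 0.2  # minority of islands methylated, as in normal cells
    effect_mean: float = 2.0  # log2 units
    effect_sd: float = 0.25
    min_effect: float = 1.2  # keeps truth peaks above the positivity threshold
    min_peak_span: int = 6  # probes; callable under the default 4-probe rule
    noise_sd: float = 0.3  # log2 units
    baseline_log2: float = 10.0
    baseline_sd: float = 2.0  # wide intensity range, as on real tiling arrays
    # polynomial in (A - baseline); gentle curvature, within ~1 log2 unit
    # across the intensity range as on real two-color arrays
    dye_bias: tuple[float, ...] = (0.0, 0.1, 0.03)
    n_differential: int = 0
    treated_group: str = "treated"
    control_group: str = "control"
    conversion_rate: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        ppr = self.probes_per_region
        if isinstance(ppr, int):
            ppr = (ppr, ppr)
        ppr = tuple(int(v) for v in ppr)
        object.__setattr__(self, "probes_per_region", ppr)
        object.__setattr__(self, "dye_bias", tuple(float(c) for c in self.dye_bias))
        if self.n_regions <= 0:
            raise ValueError("n_regions must be positive")
        if ppr[0] <= 0 or ppr[1] < ppr[0]:
            raise ValueError("probes_per_region must be a positive (low, high) range")
        if self.probe_length <= 0 or self.probe_spacing <= 0:
            raise ValueError("probe_length and probe_spacing must be positive")
        if not 0.0 <= self.peak_density <= 1.0:
            raise ValueError("peak_density must lie in [0, 1]")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must lie in [0, 1]")
        if self.n_differential < 0:
            raise ValueError("n_differential must be non-negative")


@dataclass(frozen=True)
class TruthPeak:
    """Ground truth: a methylated run of probes within one region."""

    region_id: str
    probe_span: tuple[int, int]  # (first_index, last_index) within the region
    effect: float  # log2-ratio elevation, >= 0
    group: str  # SHARED, or the single group carrying the peak

    def __post_init__(self) -> None:
        first, last = self.probe_span
        if last < first:
            raise ValueError("probe_span must satisfy first <= last")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")

    @property
    def n_probes(self) -> int:
        return self.probe_span[1] - self.probe_span[0] + 1


@dataclass
class TruthSet:
    """All truth peaks plus which of them are differential between groups."""

    peaks: list[TruthPeak]
    differential: list[tuple[TruthPeak, str]]  # direction in {hyper, hypo}
    seed: int

    def __post_init__(self) -> None:
        for peak, direction in self.differential:
            if direction not in ("hyper", "hypo"):
                raise ValueError("direction must be 'hyper' or 'hypo'")
            if peak not in self.peaks:
                raise ValueError("differential entry references unknown peak")

    def peaks_for_group(self, group: str) -> list[TruthPeak]:
        return [p for p in self.peaks if p.group in (SHARED, group)]


def generate_array_design(config: SimulationConfig) -> ProbeDesign:
    """Lay out tiled regions (alternating CpG island / promoter) on a few
    chromosomes. Deterministic for a fixed seed."""
    rng = substream(config.seed, "design")
    lo, hi = config.probes_per_region
    n_chroms = max(1, min(config.n_chromosomes, config.n_regions))
    per_chrom = math.ceil(config.n_regions / n_chroms)

    probes: list[Probe] = []
    regions: list[Region] = []
    for i in range(config.n_regions):
        chrom = f"chr{i // per_chrom + 1}"
        if i % per_chrom == 0:
            cursor = config.first_region_start
        n_probes = int(rng.integers(lo, hi + 1))
        kind = "cpg_island" if i % 2 == 0 else "promoter"
        rid = f"region_{i:05d}"
        start = cursor
        for j in range(n_probes):
            p_start = start + j * config.probe_spacing
            probes.append(
                Probe(f"{rid}_p{j:03d}", chrom, p_start, p_start + config.probe_length, rid, j)
            )
        end = start + (n_probes - 1) * config.probe_spacing + config.probe_length
        regions.append(Region(rid, chrom, start, end, kind))
        cursor = end + config.inter_region_gap
    return ProbeDesign(probes=probes, regions=regions)


def simulate_truth_methylome(design: ProbeDesign, config: SimulationConfig) -> TruthSet:
    """Draw shared methylation peaks (Bernoulli peak_density per region) and
    inject n_differential group-specific peaks into peak-free regions.

    Hyper peaks exist only in the treated group; hypo peaks only in the
    control group (i.e. they are lost in the treated sample).
    """
    if design.n_probes == 0:
        raise ValueError("design has no probes")
    rng = substream(config.seed, "truth")

    def draw_peak(region: Region, group: str) -> TruthPeak:
        n = len(design.region_probe_indices(region.region_id))
        span = min(n, int(rng.integers(config.min_peak_span, max(config.min_peak_span, n) + 1)))
        first = int(rng.integers(0, n - span + 1))
        effect = max(config.min_effect, float(rng.normal(config.effect_mean, config.effect_sd)))
        return TruthPeak(region.region_id, (first, first + span - 1), effect, group)

    peaks: list[TruthPeak] = []
    free_regions: list[Region] = []
    has_peak = rng.random(len(design.regions)) < config.peak_density
    for region, hit in zip(design.regions, has_peak):
        if hit:
            peaks.append(draw_peak(region, SHARED))
        else:
            free_regions.append(region)

    differential: list[tuple[TruthPeak, str]] = []
    if config.n_differential:
        if config.n_differential > len(free_regions):
            raise ValueError(
                f"cannot place {config.n_differential} differential peaks in "
                f"{len(free_regions)} peak-free regions"
            )
        chosen = rng.choice(len(free_regions), size=config.n_differential, replace=False)
        n_hyper = math.ceil(config.n_differential / 2)
        for k, ridx in enumerate(chosen):
            direction = "hyper" if k < n_hyper else "hypo"
            group = config.treated_group if direction == "hyper" else config.control_group
            peak = draw_peak(free_regions[int(ridx)], group)
            peaks.append(peak)
            differential.append((peak, direction))
    return TruthSet(peaks=peaks, differential=differential, seed=config.seed)


def _effect_vector(design: ProbeDesign, truth: TruthSet, group: str) -> np.ndarray:
    effect = np.zeros(design.n_probes)
    for peak in truth.peaks_for_group(group):
        idx = design.region_probe_indices(peak.region_id)
        first, last = peak.probe_span
        if last >= len(idx):
            raise RuntimeError(f"truth peak span exceeds region {peak.region_id} probe count")
        effect[idx[first : last + 1]] += peak.effect
    return effect


def simulate_sample_intensities(
    design: ProbeDesign,
    truth: TruthSet,
    group: str,
    config: SimulationConfig,
    sample_id: str | None = None,
) -> ArraySample:
    """Simulate one array's raw two-channel intensities.

    Distinct sample_ids of the same group give independent noise draws on a
    shared peak structure (replicates).
    """
    sample_id = sample_id or group
    rng = substream(config.seed, f"sample:{sample_id}")
    n = design.n_probes
    input_log2 = config.baseline_log2 + rng.normal(0.0, config.baseline_sd, n)
    effect = _effect_vector(design, truth, group)
    mira_log2 = input_log2 + effect + rng.normal(0.0, config.noise_sd, n)
    a = 0.5 * (mira_log2 + input_log2)
    bias = np.polynomial.polynomial.polyval(a - config.baseline_log2, np.asarray(config.dye_bias))
    mira_log2 = mira_log2 + bias
    return ArraySample(
        sample_id=sample_id,
        group=group,
        mira_raw=np.exp2(mira_log2),
        input_raw=np.exp2(input_log2),
    )


def generate_amplicon(
    name: str,
    length: int = 400,
    n_cpgs: int = 20,
    seed: int = 0,
    n_taqai_sites: int = 2,
) -> Amplicon:
    """Random bisulfite PCR target with a controlled number of CpGs, some of
    them inside TaqαI (TCGA) sites so COBRA has something to score."""
    if length < 4 * (n_cpgs + 1):
        raise ValueError("amplicon too short for the requested CpG count")
    rng = substream(seed, f"amplicon:{name}")
    non_c = np.array(list("ATG"))
    seq = rng.choice(non_c, size=length)  # Cs are placed explicitly below
    protected = np.zeros(length, dtype=bool)
    # place CpG (or TCGA) motifs on a non-overlapping grid, jittered
    slots = np.linspace(8, length - 8, n_cpgs).astype(int)
    for k, pos in enumerate(slots):
        pos = int(pos) + int(rng.integers(-2, 3))
        if k < n_taqai_sites:
            seq[pos - 1 : pos + 3] = list("TCGA")
            protected[pos - 1 : pos + 3] = True
        else:
            seq[pos : pos + 2] = list("CG")
            protected[pos : pos + 2] = True
    # sprinkle non-CpG cytosines (conversion-efficiency QC needs them):
    # a C is safe when neither it nor its neighbours touch a motif and the
    # next base is not G (which would create a new CpG)
    for i in range(1, length - 1):
        if protected[i - 1 : i + 2].any() or seq[i + 1] == "G":
            continue
        if rng.random() < 0.10:
            seq[i] = "C"
    return Amplicon(name=name, sequence="".join(seq))


def simulate_bisulfite_clones(
    amplicon: Amplicon,
    per_cpg_prob: Sequence[float],
    n_clones: int,
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Draw clones: Bernoulli methylation per CpG, then bisulfite conversion
    with the configured success rate at unmethylated cytosines.

    Returns ([(clone_id, read_sequence), ...], truth) where truth is a
    (n_clones, n_cpgs) boolean array of methylation states.
    """
    probs = np.asarray(per_cpg_prob, dtype=float)
    if probs.size != len(amplicon.cpg_positions):
        raise ValueError(
            f"per_cpg_prob has {probs.size} entries but amplicon "
            f"{amplicon.name} has {len(amplicon.cpg_positions)} CpGs"
        )
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("per-CpG probabilities must lie in [0, 1]")
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    rng = substream(config.seed, f"clones:{amplicon.name}")
    truth = rng.random((n_clones, probs.size)) < probs
    clones = []
    cpg_positions = np.asarray(amplicon.cpg_positions)
    for i in range(n_clones):
        methylated = set(int(p) for p in cpg_positions[truth[i]])
        read = bisulfite_convert(
            amplicon.sequence, methylated, conversion_rate=config.conversion_rate, rng=rng
        )
        clones.append((f"{amplicon.name}_clone{i:03d}", read))
    return clones, truth
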