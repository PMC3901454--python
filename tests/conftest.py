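import numpy as np
import pytest

from mirachip.design import ArraySample, Probe, ProbeDesign, Region


def build_design(
    probes_per_region,
    spacing=100,
    length=50,
    region_start=1000,
    chrom="chr1",
    starts_per_region=None,
):
    """Construct a small design directly. `probes_per_region` is a list of
    probe counts, one region each; `starts_per_region` optionally gives
    explicit probe start coordinates (to create spacing violations)."""
    probes, regions = [], []
    cursor = region_start
    for r, n in enumerate(probes_per_region):
        rid = f"r{r}"
        if starts_per_region is not None:
            starts = starts_per_region[r]
        else:
            starts = [cursor + j * spacing for j in range(n)]
        for j, s in enumerate(starts):
            probes.append(Probe(f"{rid}_p{j}", chrom, s, s + length, rid, j))
        regions.append(Region(rid, chrom, starts[0], starts[-1] + length, "cpg_island"))
        cursor = starts[-1] + length + 10_000
    return ProbeDesign(probes=probes, regions=regions)


def normalized_sample(ratios, sample_id="s", group="g"):
    """An ArraySample carrying given normalized log2 ratios."""
    ratios = np.asarray(ratios, dtype=float)
    return ArraySample(
        sample_id=sample_id,
        group=group,
        mira_raw=np.exp2(ratios) * 100.0,
        input_raw=np.full(ratios.size, 100.0),
        log2_ratio=ratios,
        normalized=True,
    )


def brute_force_peaks(design, flags, min_positive=4, max_gaps=1, max_spacing=500):
    """Independent oracle: enumerate every probe interval within each
    region, keep those satisfying the peak predicate (boundary-positive,
    at most max_gaps isolated single-probe interior gaps, all adjacent
    spacings within max_spacing, >= min_positive positives), then select
    non-overlapping intervals greedily by (smallest start, largest end).

    Returns a list of (region_id, first_global_index, last_global_index).
    """
    flags = np.asarray(flags, dtype=bool)
    chosen = []
    for region in design.regions:
        idx = design.region_probe_indices(region.region_id)
        m = len(idx)
        f = [bool(flags[i]) for i in idx]

        def valid(a, b):
            if not (f[a] and f[b]):
                return False
            gaps = [j for j in range(a, b + 1) if not f[j]]
            if len(gaps) > max_gaps:
                return False
            for g1, g2 in zip(gaps, gaps[1:]):
                if g2 == g1 + 1:  # multi-probe gap
                    return False
            for j in range(a, b):
                pa, pb = design.probes[idx[j]], design.probes[idx[j + 1]]
                if pb.start - pa.end > max_spacing:
                    return False
            return sum(f[a : b + 1]) >= min_positive

        intervals = sorted(
            ((a, b) for a in range(m) for b in range(a, m) if valid(a, b)),
            key=lambda ab: (ab[0], -ab[1]),
        )
        taken = []
        for a, b in intervals:
            if all(b < ta or a > tb for ta, tb in taken):
                taken.append((a, b))
        for a, b in sorted(taken):
            chosen.append((region.region_id, idx[a], idx[b]))
    return chosen


@pytest.fixture
def small_design():
    return build_design([8, 10, 6])
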