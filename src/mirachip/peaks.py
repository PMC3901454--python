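"""Methylation peak calling: runs of positive probes with gap tolerance.

The rule: a probe is positive when its normalized log2(MIRA/input) ratio
exceeds 2-fold (log2 ratio > 1, strict); a peak is at least four positive
probes in a row, tolerating at most one single-probe gap strictly inside
the run. Peaks never start or end on a gap probe, never cross tiled-region
boundaries, and break whenever consecutive probes are further apart than
`max_spacing` bp. When several valid windows overlap, the scan keeps the
leftmost-starting, longest one and continues after it, so emitted peaks are
maximal and mutually non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ArraySample, ProbeDesign

__all__ = [
    "MethylationPeak",
    "flag_positive_probes",
    "call_peaks",
    "call_sample_peaks",
    "score_peak_in_sample",
]

#: log2 ratio above which a probe counts as positive ("above 2-fold")
POSITIVITY_THRESHOLD = 1.0


@dataclass
class MethylationPeak:
    """A called run of positive probes in one sample."""

    sample_id: str
    chrom: str
    start: int  # bp, 0-based: start of first member probe
    end: int  # bp, half-open: end of last member probe
    region_id: str
    probe_indices: list[int]  # contiguous design-order indices, gaps included
    n_positive: int
    n_gaps: int
    mean_log2_ratio: float

    @property
    def n_probes(self) -> int:
        return len(self.probe_indices)


def flag_positive_probes(sample: ArraySample, threshold: float = POSITIVITY_THRESHOLD) -> np.ndarray:
    """Boolean vector: log2_ratio strictly above `threshold`.

    Refuses unnormalized samples — positivity is defined on normalized
    ratios only.
    """
    if not sample.normalized or sample.log2_ratio is None:
        raise ValueError(
            f"sample {sample.sample_id} is not normalized; "
            "run loess_normalize + quantile_normalize first"
        )
    return sample.log2_ratio > threshold


def call_peaks(
    design: ProbeDesign,
    flags: np.ndarray,
    log2_ratio: np.ndarray | None = None,
    *,
    min_positive: int = 4,
    max_gaps: int = 1,
    max_spacing: int = 500,
    sample_id: str = "",
) -> list[MethylationPeak]:
    """Scan each region in design order and emit maximal gap-tolerant runs
    with at least `min_positive` positive probes.

    A run may absorb up to `max_gaps` isolated single-probe gaps strictly in
    its interior (two negative probes in a row always end it). Adjacent
    probes whose genomic gap (next start - previous end) exceeds
    `max_spacing` bp never share a run. mean_log2_ratio averages over every
    member probe, gap probes included (NaN when ratios are not supplied).
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != design.n_probes:
        raise ValueError(f"flags length {flags.size} != probe count {design.n_probes}")
    if log2_ratio is not None:
        log2_ratio = np.asarray(log2_ratio, dtype=float)
        if log2_ratio.size != design.n_probes:
            raise ValueError("log2_ratio length mismatch")

    peaks: list[MethylationPeak] = []
    for region in design.regions:
        idx = design.region_probe_indices(region.region_id)
        m = len(idx)
        f = flags[np.asarray(idx, dtype=int)] if m else np.zeros(0, bool)

        def spacing_ok(a: int, b: int) -> bool:
            pa, pb = design.probes[idx[a]], design.probes[idx[b]]
            return pb.start - pa.end <= max_spacing

        i = 0
        while i < m:
            if not f[i]:
                i += 1
                continue
            # extend maximally from start i
            end = i
            gaps_used = 0
            k = i
            while True:
                nxt = k + 1
                if nxt >= m or not spacing_ok(k, nxt):
                    break
                if f[nxt]:
                    k = end = nxt
                elif (
                    gaps_used < max_gaps
                    and nxt + 1 < m
                    and f[nxt + 1]
                    and spacing_ok(nxt, nxt + 1)
                ):
                    gaps_used += 1
                    k = end = nxt + 1
                else:
                    break
            member_local = list(range(i, end + 1))
            n_positive = int(f[i : end + 1].sum())
            if n_positive >= min_positive:
                member = [idx[j] for j in member_local]
                first_p = design.probes[member[0]]
                last_p = design.probes[member[-1]]
                if log2_ratio is None:
                    mean_ratio = float("nan")
                else:
                    mean_ratio = float(log2_ratio[member].mean())
                peaks.append(
                    MethylationPeak(
                        sample_id=sample_id,
                        chrom=region.chrom,
                        start=first_p.start,
                        end=last_p.end,
                        region_id=region.region_id,
                        probe_indices=member,
                        n_positive=n_positive,
                        n_gaps=len(member) - n_positive,
                        mean_log2_ratio=mean_ratio,
                    )
                )
                i = end + 1
            else:
                # too few positives from this start: a later start inside the
                # window may still seed a valid run, so advance one probe only
                i += 1
    return peaks


def call_sample_peaks(
    design: ProbeDesign,
    sample: ArraySample,
    threshold: float = POSITIVITY_THRESHOLD,
    **kwargs,
) -> list[MethylationPeak]:
    """Convenience: flag positives then call peaks for one normalized sample."""
    flags = flag_positive_probes(sample, threshold=threshold)
    return call_peaks(
        design, flags, sample.log2_ratio, sample_id=sample.sample_id, **kwargs
    )


def score_peak_in_sample(peak: MethylationPeak, other: ArraySample) -> float:
    """Mean of `other`'s normalized log2 ratios over the peak's own probe
    footprint — how the peak's territory looks in another sample."""
    if not other.normalized or other.log2_ratio is None:
        raise ValueError(f"sample {other.sample_id} is not normalized")
    idx = np.asarray(peak.probe_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("peak has an empty probe footprint")
    if idx.min() < 0 or idx.max() >= other.n_probes:
        raise IndexError(
            f"peak probe indices [{idx.min()}, {idx.max()}] out of range for "
            f"sample {other.sample_id} with {other.n_probes} probes"
        )
    return float(other.log2_ratio[idx].mean())
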