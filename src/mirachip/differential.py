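"""Treated-vs-control differential methylation by the log2(3) rule.

For each candidate peak footprint, the mean normalized log2 ratio over the
footprint is computed in both samples; the peak is hypermethylated when the
treated - control difference strictly exceeds log2(3) ≈ 1.585 and
hypomethylated when it is strictly below -log2(3). This is a fixed
effect-size threshold, not a statistical test: no variance model, no
p-values, no multiple-testing correction.

Candidates are the union of both samples' called peaks (scoring only the
treated sample's peaks could never detect loss of a control-only peak);
overlapping peaks from the two samples are merged on the union of their
probe footprints before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ArraySample, ProbeDesign
from .peaks import MethylationPeak, score_peak_in_sample

__all__ = [
    "DEFAULT_DELTA_THRESHOLD",
    "DifferentialCall",
    "ComparisonSummary",
    "compare_sample_pair",
    "summarize_comparisons",
    "summary_table",
    "calls_table",
]

DEFAULT_DELTA_THRESHOLD = math.log2(3.0)  # 1.5849625007211562


@dataclass
class DifferentialCall:
    """One peak footprint whose mean signal differs beyond the threshold."""

    peak: MethylationPeak  # merged candidate footprint
    mean_treated: float
    mean_control: float
    delta: float  # treated - control
    direction: str  # "hyper" or "hypo"
    comparison_id: str

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if (self.delta > 0) != (self.direction == "hyper"):
            raise ValueError("direction inconsistent with the sign of delta")


@dataclass
class ComparisonSummary:
    """Hyper/hypo call counts for one treated-vs-control comparison."""

    comparison_id: str
    treated_id: str
    control_id: str
    n_hyper: int
    n_hypo: int
    calls: list[DifferentialCall]

    @property
    def n_calls(self) -> int:
        return self.n_hyper + self.n_hypo


def _merge_candidates(
    design: ProbeDesign,
    treated_peaks: list[MethylationPeak],
    control_peaks: list[MethylationPeak],
) -> list[MethylationPeak]:
    """Union candidate footprints: peaks from either sample, merged within a
    region whenever their contiguous probe-index ranges overlap."""
    by_region: dict[str, list[MethylationPeak]] = {}
    for p in list(treated_peaks) + list(control_peaks):
        by_region.setdefault(p.region_id, []).append(p)

    merged: list[MethylationPeak] = []
    for region_id in sorted(by_region):
        spans = sorted(
            ((min(p.probe_indices), max(p.probe_indices), p) for p in by_region[region_id]),
            key=lambda t: (t[0], t[1]),
        )
        current_lo, current_hi, sources = spans[0][0], spans[0][1], [spans[0][2]]
        groups = []
        for lo, hi, p in spans[1:]:
            if lo <= current_hi:  # shares at least one probe
                current_hi = max(current_hi, hi)
                sources.append(p)
            else:
                groups.append((current_lo, current_hi, sources))
                current_lo, current_hi, sources = lo, hi, [p]
        groups.append((current_lo, current_hi, sources))

        for lo, hi, sources in groups:
            member = list(range(lo, hi + 1))
            first_p, last_p = design.probes[lo], design.probes[hi]
            merged.append(
                MethylationPeak(
                    sample_id="+".join(sorted({p.sample_id for p in sources})),
                    chrom=first_p.chrom,
                    start=first_p.start,
                    end=last_p.end,
                    region_id=region_id,
                    probe_indices=member,
                    n_positive=max(p.n_positive for p in sources),
                    n_gaps=max(p.n_gaps for p in sources),
                    mean_log2_ratio=float("nan"),
                )
            )
    return merged


def compare_sample_pair(
    treated: ArraySample,
    control: ArraySample,
    treated_peaks: list[MethylationPeak],
    control_peaks: list[MethylationPeak],
    design: ProbeDesign | None = None,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    comparison_id: str | None = None,
) -> ComparisonSummary:
    """Score every candidate footprint in both samples and keep those whose
    signal difference strictly exceeds `delta_threshold` in magnitude.

    `design` is needed only to rebuild merged footprint coordinates; if
    omitted, a minimal stand-in is built from the peaks themselves (merging
    then uses probe indices only).
    """
    if treated.n_probes != control.n_probes:
        raise ValueError(
            f"samples {treated.sample_id} and {control.sample_id} are from "
            "different designs (probe counts differ)"
        )
    comparison_id = comparison_id or f"{treated.sample_id}_vs_{control.sample_id}"

    if design is not None:
        candidates = _merge_candidates(design, treated_peaks, control_peaks)
    else:
        candidates = _merge_candidates_designless(treated_peaks, control_peaks)

    calls: list[DifferentialCall] = []
    for peak in candidates:
        mean_t = score_peak_in_sample(peak, treated)
        mean_c = score_peak_in_sample(peak, control)
        delta = mean_t - mean_c
        if delta > delta_threshold:
            direction = "hyper"
        elif delta < -delta_threshold:
            direction = "hypo"
        else:
            continue
        calls.append(
            DifferentialCall(
                peak=peak,
                mean_treated=mean_t,
                mean_control=mean_c,
                delta=delta,
                direction=direction,
                comparison_id=comparison_id,
            )
        )
    n_hyper = sum(1 for c in calls if c.direction == "hyper")
    return ComparisonSummary(
        comparison_id=comparison_id,
        treated_id=treated.sample_id,
        control_id=control.sample_id,
        n_hyper=n_hyper,
        n_hypo=len(calls) - n_hyper,
        calls=calls,
    )


def _merge_candidates_designless(
    treated_peaks: list[MethylationPeak], control_peaks: list[MethylationPeak]
) -> list[MethylationPeak]:
    # merged coordinates are taken from the covering source peaks
    by_region: dict[str, list[MethylationPeak]] = {}
    for p in list(treated_peaks) + list(control_peaks):
        by_region.setdefault(p.region_id, []).append(p)
    merged = []
    for region_id in sorted(by_region):
        spans = sorted(
            ((min(p.probe_indices), max(p.probe_indices), p) for p in by_region[region_id]),
            key=lambda t: (t[0], t[1]),
        )
        lo, hi, sources = spans[0][0], spans[0][1], [spans[0][2]]
        groups = []
        for a, b, p in spans[1:]:
            if a <= hi:
                hi = max(hi, b)
                sources.append(p)
            else:
                groups.append((lo, hi, sources))
                lo, hi, sources = a, b, [p]
        groups.append((lo, hi, sources))
        for lo, hi, sources in groups:
            merged.append(
                MethylationPeak(
                    sample_id="+".join(sorted({p.sample_id for p in sources})),
                    chrom=sources[0].chrom,
                    start=min(p.start for p in sources),
                    end=max(p.end for p in sources),
                    region_id=region_id,
                    probe_indices=list(range(lo, hi + 1)),
                    n_positive=max(p.n_positive for p in sources),
                    n_gaps=max(p.n_gaps for p in sources),
                    mean_log2_ratio=float("nan"),
                )
            )
    return merged


def summarize_comparisons(
    pairs: list[tuple[ArraySample, ArraySample, list[MethylationPeak], list[MethylationPeak]]],
    design: ProbeDesign | None = None,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    comparison_ids: list[str] | None = None,
) -> list[ComparisonSummary]:
    """Run compare_sample_pair over many (treated, control) pairs; results
    are ordered by comparison_id and ids must be unique."""
    if comparison_ids is not None and len(comparison_ids) != len(pairs):
        raise ValueError("comparison_ids length must match pairs")
    summaries = []
    for k, (treated, control, t_peaks, c_peaks) in enumerate(pairs):
        cid = comparison_ids[k] if comparison_ids is not None else None
        summaries.append(
            compare_sample_pair(
                treated, control, t_peaks, c_peaks,
                design=design, delta_threshold=delta_threshold, comparison_id=cid,
            )
        )
    ids = [s.comparison_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate comparison_id(s): {dupes}")
    return sorted(summaries, key=lambda s: s.comparison_id)


def summary_table(summaries: list[ComparisonSummary]) -> pd.DataFrame:
    """One row per comparison: hyper and hypo counts."""
    return pd.DataFrame(
        {
            "comparison_id": [s.comparison_id for s in summaries],
            "treated_id": [s.treated_id for s in summaries],
            "control_id": [s.control_id for s in summaries],
            "n_hyper": [s.n_hyper for s in summaries],
            "n_hypo": [s.n_hypo for s in summaries],
        }
    )


def calls_table(summary: ComparisonSummary) -> pd.DataFrame:
    """One row per differential call, ready to write as TSV."""
    rows = [
        {
            "comparison_id": c.comparison_id,
            "chrom": c.peak.chrom,
            "start": c.peak.start,
            "end": c.peak.end,
            "region_id": c.peak.region_id,
            "mean_treated": c.mean_treated,
            "mean_control": c.mean_control,
            "delta": c.delta,
            "direction": c.direction,
        }
        for c in summary.calls
    ]
    cols = [
        "comparison_id", "chrom", "start", "end", "region_id",
        "mean_treated", "mean_control", "delta", "direction",
    ]
    return pd.DataFrame(rows, columns=cols)
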