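"""Two-channel normalization: per-array loess, then cross-sample quantile.

The order matters and mirrors standard two-color tiling-array practice:
loess is fit on each array independently to remove intensity-dependent dye
bias from the MA representation, then the log2 ratios of all arrays in the
experiment (treated and control alike) are quantile-normalized so their
distributions are identical and the downstream fold-change thresholds mean
the same thing in every sample.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import ArraySample

__all__ = ["loess_normalize", "quantile_normalize"]


def loess_normalize(sample: ArraySample, span: float = 0.3, iterations: int = 3) -> ArraySample:
    """Remove intensity-dependent dye bias from one array.

    Computes M = log2(mira/input) and A = (log2 mira + log2 input)/2, fits a
    robust locally weighted regression of M on A (`span` is the fraction of
    probes in each local window, `iterations` the number of robustifying
    reweights), and returns a new sample with log2_ratio = M - fit(A).
    The input sample is not modified and `normalized` stays False until the
    quantile pass.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    n = sample.n_probes
    min_probes = max(8, math.ceil(4.0 / span))
    if n < min_probes:
        raise ValueError(
            f"loess_normalize needs at least {min_probes} probes at span {span}; got {n}"
        )
    log_mira = np.log2(sample.mira_raw)
    log_input = np.log2(sample.input_raw)
    m = log_mira - log_input
    a = 0.5 * (log_mira + log_input)
    a_range = float(np.ptp(a))
    if a_range == 0.0:
        fit = np.full(n, m.mean())
    else:
        delta = 0.01 * a_range if n > 200 else 0.0
        fit = lowess(
            m, a, frac=span, it=iterations, delta=delta, return_sorted=False
        )
    return replace(sample, log2_ratio=m - fit, normalized=False)


def quantile_normalize(samples: list[ArraySample]) -> list[ArraySample]:
    """Force every sample's log2-ratio distribution onto the common
    reference (the across-sample mean of order statistics), preserving
    within-sample ranks; tied values receive the mean of their tied
    reference quantiles.

    Returns new samples flagged `normalized=True`. Idempotent.
    """
    if not samples:
        raise ValueError("quantile_normalize needs at least one sample")
    n = samples[0].n_probes
    for s in samples:
        if s.log2_ratio is None:
            raise ValueError(f"sample {s.sample_id}: log2_ratio not populated (run loess first)")
        if s.n_probes != n:
            raise ValueError("samples have mismatched probe counts")

    sorted_matrix = np.column_stack([np.sort(s.log2_ratio) for s in samples])
    reference = sorted_matrix.mean(axis=1)

    out = []
    for s in samples:
        v = s.log2_ratio
        order = np.argsort(v, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = reference
        # ties: average the reference values assigned within each tied group
        v_sorted = v[order]
        group_starts = np.flatnonzero(np.r_[True, np.diff(v_sorted) != 0])
        group_means = np.add.reduceat(reference, group_starts) / np.diff(
            np.r_[group_starts, n]
        )
        tied_ref = np.repeat(group_means, np.diff(np.r_[group_starts, n]))
        mapped[order] = tied_ref
        out.append(replace(s, log2_ratio=mapped, normalized=True))
    return out
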