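"""Array geometry: tiled probes grouped into CpG-island / promoter regions.

All coordinates are 0-based half-open throughout the package; BED output
needs no shift, 1-based formats add 1 to start on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["Probe", "Region", "ProbeDesign", "ArraySample"]

REGION_KINDS = ("cpg_island", "promoter")


@dataclass(frozen=True)
class Probe:
    """One tiled oligo on the array."""

    probe_id: str
    chrom: str
    start: int  # bp, 0-based
    end: int  # bp, half-open
    region_id: str
    index_in_region: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"probe {self.probe_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Region:
    """A tiled unit: a CpG island or a RefSeq promoter window."""

    region_id: str
    chrom: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"region kind must be one of {REGION_KINDS}")
        if not self.start < self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")


@dataclass
class ProbeDesign:
    """Ordered probes plus the regions they tile.

    Invariants checked on construction: every probe's region exists, probes
    within a region are sorted, non-overlapping and consecutively indexed
    from 0, and regions on one chromosome are sorted by start.
    """

    probes: list[Probe]
    regions: list[Region]
    _region_index: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        region_ids = {r.region_id for r in self.regions}
        if len(region_ids) != len(self.regions):
            raise ValueError("duplicate region_id in design")
        index: dict[str, list[int]] = {r.region_id: [] for r in self.regions}
        for i, p in enumerate(self.probes):
            if p.region_id not in region_ids:
                raise ValueError(f"probe {p.probe_id} references unknown region {p.region_id}")
            index[p.region_id].append(i)
        for rid, idx in index.items():
            probes = [self.probes[i] for i in idx]
            for j, p in enumerate(probes):
                if p.index_in_region != j:
                    raise ValueError(f"region {rid}: index_in_region not consecutive from 0")
                if j and p.start < probes[j - 1].end:
                    raise ValueError(f"region {rid}: probes overlap or are unsorted")
        by_chrom: dict[str, list[Region]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            starts = [r.start for r in rs]
            if starts != sorted(starts):
                raise ValueError(f"regions on {chrom} are not sorted")
        self._region_index = index

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def region_probe_indices(self, region_id: str) -> list[int]:
        """Design-order indices of the probes tiling one region."""
        return self._region_index[region_id]

    def probe_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in self.probes],
                "chrom": [p.chrom for p in self.probes],
                "start": [p.start for p in self.probes],
                "end": [p.end for p in self.probes],
                "region_id": [p.region_id for p in self.probes],
            }
        )

    def write_probe_tsv(self, path: str | Path) -> None:
        self.probe_table().to_csv(path, sep="\t", index=False)

    def write_region_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t.\t{r.kind}\n")

    @classmethod
    def from_probe_tsv(cls, path: str | Path, regions: Iterable[Region] | None = None) -> "ProbeDesign":
        """Rebuild a design from the probe table written by write_probe_tsv.

        If `regions` is omitted, minimal regions are inferred as the span of
        each region's probes (kind defaults to cpg_island).
        """
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "region_id": str})
        counters: dict[str, int] = {}
        probes = []
        for row in df.itertuples(index=False):
            j = counters.get(row.region_id, 0)
            counters[row.region_id] = j + 1
            probes.append(
                Probe(str(row.probe_id), row.chrom, int(row.start), int(row.end), row.region_id, j)
            )
        if regions is None:
            regions = []
            for rid, grp in df.groupby("region_id", sort=False):
                regions.append(
                    Region(str(rid), grp["chrom"].iloc[0], int(grp["start"].min()), int(grp["end"].max()), "cpg_island")
                )
            regions.sort(key=lambda r: (r.chrom, r.start))
        return cls(probes=probes, regions=list(regions))


@dataclass
class ArraySample:
    """One hybridization: per-probe MIRA and input channel intensities.

    `log2_ratio` is populated by normalization; `normalized` is set once the
    sample has been through the full loess + quantile pass and is required
    before any thresholding happens.
    """

    sample_id: str
    group: str
    mira_raw: np.ndarray
    input_raw: np.ndarray
    log2_ratio: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.mira_raw = np.asarray(self.mira_raw, dtype=float)
        self.input_raw = np.asarray(self.input_raw, dtype=float)
        if self.mira_raw.shape != self.input_raw.shape or self.mira_raw.ndim != 1:
            raise ValueError("channel vectors must be 1-D and equally long")
        if np.any(self.mira_raw <= 0) or np.any(self.input_raw <= 0):
            raise ValueError(f"sample {self.sample_id}: raw intensities must be strictly positive")
        if self.log2_ratio is not None:
            self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
            if self.log2_ratio.shape != self.mira_raw.shape:
                raise ValueError("log2_ratio length mismatch")

    @property
    def n_probes(self) -> int:
        return self.mira_raw.size

    def raw_log2_ratio(self) -> np.ndarray:
        """log2(MIRA/input) before any correction."""
        return np.log2(self.mira_raw) - np.log2(self.input_raw)
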