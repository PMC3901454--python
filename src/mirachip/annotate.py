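"""Annotation of peaks against promoter windows and CpG islands.

Promoters are defined as -2.4 kb to +0.6 kb around the transcription start
site (strand-aware, clipped at the chromosome start); overlap is at least
one base pair of half-open interval intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "TranscriptRecord",
    "PromoterWindow",
    "CpGIslandRecord",
    "AnnotatedPeak",
    "read_transcript_table",
    "read_cpg_islands",
    "promoter_window",
    "annotate_peaks",
    "annotation_table",
]

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 2400
DEFAULT_DOWNSTREAM = 600


@dataclass(frozen=True)
class TranscriptRecord:
    name: str
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    tx_start: int  # 0-based
    tx_end: int  # half-open

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.name}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"transcript {self.name}: tx_start must be < tx_end")


@dataclass(frozen=True)
class PromoterWindow:
    transcript: TranscriptRecord
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class CpGIslandRecord:
    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"CpG island {self.name}: start must be < end")


def read_transcript_table(path: str | Path, dialect: str = "bed") -> list[TranscriptRecord]:
    """Read transcripts from a BED6 file or a UCSC refFlat-like table.

    Both dialects are 0-based half-open per UCSC convention. Records without
    a +/- strand are rejected with a logged warning; structurally malformed
    lines raise with their line number.
    """
    if dialect not in ("bed", "refflat"):
        raise ValueError("dialect must be 'bed' or 'refflat'")
    records: list[TranscriptRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed":
                    if len(fields) < 6:
                        raise ValueError("expected >=6 BED columns")
                    chrom, start, end, name, _score, strand = fields[:6]
                    gene = name
                    start, end = int(start), int(end)
                else:  # refFlat: geneName name chrom strand txStart txEnd ...
                    if len(fields) < 6:
                        raise ValueError("expected >=6 refFlat columns")
                    gene, name, chrom, strand, start, end = fields[:6]
                    start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if strand not in ("+", "-"):
                logger.warning("%s:%d: record %s has no usable strand (%r); skipped",
                               path, lineno, name, strand)
                continue
            records.append(TranscriptRecord(name, gene, chrom, strand, start, end))
    return records


def read_cpg_islands(path: str | Path) -> list[CpGIslandRecord]:
    """Read CpG islands from BED3+ (name optional, auto-numbered)."""
    islands = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from exc
            name = fields[3] if len(fields) > 3 else f"CpG_{len(islands) + 1}"
            islands.append(CpGIslandRecord(chrom, start, end, name))
    return islands


def promoter_window(
    t: TranscriptRecord,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> PromoterWindow:
    """Strand-aware promoter window around the TSS, clipped at 0.

    + strand: TSS = tx_start, window [TSS - upstream, TSS + downstream);
    - strand: TSS = tx_end, window [TSS - downstream, TSS + upstream).
    """
    if t.strand == "+":
        tss = t.tx_start
        start, end = tss - upstream, tss + downstream
    else:
        tss = t.tx_end
        start, end = tss - downstream, tss + upstream
    return PromoterWindow(transcript=t, chrom=t.chrom, start=max(0, start), end=end)


@dataclass
class AnnotatedPeak:
    """A peak (or differential call footprint) with its annotation."""

    peak: object  # anything with .chrom/.start/.end
    promoter_genes: list[str]
    cpg_islands: list[str]
    category: str  # promoter | cpg_island | both | intergenic


def annotate_peaks(
    peaks: list,
    transcripts: list[TranscriptRecord],
    islands: list[CpGIslandRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[AnnotatedPeak]:
    """Attach overlapping promoter gene names and CpG island names to each
    peak (>= 1 bp half-open overlap) plus a category. Gene names are sorted
    alphabetically and deduplicated. Peaks on chromosomes absent from both
    annotation sets fall back to 'intergenic' with a warning."""
    promoter_trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        w = promoter_window(t, upstream=upstream, downstream=downstream)
        promoter_trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, t.gene)
    island_trees: dict[str, IntervalTree] = {}
    for isl in islands:
        island_trees.setdefault(isl.chrom, IntervalTree()).addi(isl.start, isl.end, isl.name)

    annotated = []
    warned_chroms: set[str] = set()
    for peak in peaks:
        chrom, start, end = peak.chrom, peak.start, peak.end
        if chrom not in promoter_trees and chrom not in island_trees:
            if chrom not in warned_chroms:
                logger.warning("chromosome %s absent from annotation; peaks there are intergenic", chrom)
                warned_chroms.add(chrom)
        genes = sorted({iv.data for iv in promoter_trees.get(chrom, IntervalTree()).overlap(start, end)})
        isl_names = sorted({iv.data for iv in island_trees.get(chrom, IntervalTree()).overlap(start, end)})
        if genes and isl_names:
            category = "both"
        elif genes:
            category = "promoter"
        elif isl_names:
            category = "cpg_island"
        else:
            category = "intergenic"
        annotated.append(AnnotatedPeak(peak, genes, isl_names, category))
    return annotated


def annotation_table(annotated: list[AnnotatedPeak]) -> pd.DataFrame:
    """One row per peak; gene and island lists semicolon-joined."""
    return pd.DataFrame(
        {
            "chrom": [a.peak.chrom for a in annotated],
            "start": [a.peak.start for a in annotated],
            "end": [a.peak.end for a in annotated],
            "promoter_genes": [";".join(a.promoter_genes) for a in annotated],
            "cpg_islands": [";".join(a.cpg_islands) for a in annotated],
            "category": [a.category for a in annotated],
        }
    )
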