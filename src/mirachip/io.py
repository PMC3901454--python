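"""Plain-text I/O: probe intensity TSVs, peak BED, bedGraph, truth JSON,
clone FASTA. All coordinates written 0-based half-open (BED convention)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ArraySample, ProbeDesign
from .peaks import MethylationPeak
from .simulate import TruthSet

__all__ = [
    "write_intensities",
    "read_intensities",
    "write_normalized_tsv",
    "write_bedgraph",
    "write_peaks_bed",
    "write_truth_json",
    "read_truth_json",
    "write_clone_fasta",
    "read_clone_fasta",
]

INTENSITY_COLUMNS = ("probe_id", "mira_raw", "input_raw")


def write_intensities(sample: ArraySample, design: ProbeDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in design.probes],
            "mira_raw": sample.mira_raw,
            "input_raw": sample.input_raw,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_intensities(
    path: str | Path, design: ProbeDesign, sample_id: str, group: str = ""
) -> ArraySample:
    """Read a two-channel intensity TSV (columns probe_id, mira_raw,
    input_raw) and align it to the design's probe order by probe_id."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = df.set_index("probe_id")
    order = [p.probe_id for p in design.probes]
    absent = set(order) - set(df.index)
    if absent:
        raise ValueError(f"{path}: {len(absent)} design probes absent (e.g. {sorted(absent)[:3]})")
    df = df.loc[order]
    return ArraySample(
        sample_id=sample_id,
        group=group,
        mira_raw=df["mira_raw"].to_numpy(float),
        input_raw=df["input_raw"].to_numpy(float),
    )


def write_normalized_tsv(samples: list[ArraySample], design: ProbeDesign, path: str | Path) -> None:
    """Matrix of normalized log2 ratios, one column per sample."""
    data = {"probe_id": [p.probe_id for p in design.probes]}
    for s in samples:
        if s.log2_ratio is None:
            raise ValueError(f"sample {s.sample_id} has no log2_ratio")
        data[s.sample_id] = s.log2_ratio
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_bedgraph(sample: ArraySample, design: ProbeDesign, path: str | Path) -> None:
    if sample.log2_ratio is None:
        raise ValueError(f"sample {sample.sample_id} has no log2_ratio")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{sample.sample_id}"\n')
        for p, v in zip(design.probes, sample.log2_ratio):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{v:.6f}\n")


def write_peaks_bed(peaks: list[MethylationPeak], path: str | Path) -> None:
    """BED6 peaks plus a TSV sidecar (<path>.tsv) with the extra columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in peaks:
            score = int(round(1000 * min(1.0, max(0.0, p.mean_log2_ratio / 4.0))))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.sample_id}:{p.region_id}\t{score}\t.\n"
            )
    side = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "sample_id": [p.sample_id for p in peaks],
            "region_id": [p.region_id for p in peaks],
            "n_positive": [p.n_positive for p in peaks],
            "n_gaps": [p.n_gaps for p in peaks],
            "mean_log2_ratio": [p.mean_log2_ratio for p in peaks],
        }
    )
    side.to_csv(path.with_suffix(path.suffix + ".tsv"), sep="\t", index=False, float_format="%.6f")


def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "peaks": [asdict(p) for p in truth.peaks],
        "differential": [
            {"peak": asdict(p), "direction": d} for p, d in truth.differential
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_json(path: str | Path) -> TruthSet:
    from .simulate import TruthPeak

    with open(path) as fh:
        payload = json.load(fh)

    def mk(p: dict) -> TruthPeak:
        return TruthPeak(p["region_id"], tuple(p["probe_span"]), p["effect"], p["group"])

    peaks = [mk(p) for p in payload["peaks"]]
    index = {(p.region_id, p.probe_span, p.group): p for p in peaks}
    differential = [
        (index[(d["peak"]["region_id"], tuple(d["peak"]["probe_span"]), d["peak"]["group"])],
         d["direction"])
        for d in payload["differential"]
    ]
    return TruthSet(peaks=peaks, differential=differential, seed=payload["seed"])


def write_clone_fasta(clones: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for clone_id, seq in clones:
            fh.write(f">{clone_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_clone_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
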