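"""End-to-end orchestration: simulate → normalize → call → compare →
annotate → report, and the bisulfite verification sub-pipeline.

Runs are deterministic: identical config + seed give byte-identical data
files (no timestamps are written)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import (
    CpGIslandRecord,
    TranscriptRecord,
    annotate_peaks,
    annotation_table,
    read_cpg_islands,
    read_transcript_table,
)
from .bisulfite import (
    Amplicon,
    CloneAlignmentError,
    MethylationMatrix,
    align_and_call_clone,
    cobra_site_analysis,
    percent_methylation,
    render_lollipop,
)
from .design import ArraySample, ProbeDesign
from .differential import DEFAULT_DELTA_THRESHOLD, summarize_comparisons, summary_table, calls_table
from .io import (
    read_clone_fasta,
    read_intensities,
    write_clone_fasta,
    write_intensities,
    write_normalized_tsv,
    write_peaks_bed,
    write_truth_json,
)
from .normalize import loess_normalize, quantile_normalize
from .peaks import call_sample_peaks
from .simulate import (
    SimulationConfig,
    generate_amplicon,
    generate_array_design,
    simulate_bisulfite_clones,
    simulate_sample_intensities,
    simulate_truth_methylome,
)

__all__ = ["PipelineConfig", "RunReport", "run_chip_pipeline", "run_bisulfite_report"]

logger = logging.getLogger(__name__)

MODES = ("simulate", "chip", "bisulfite", "full")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    mode: str = "simulate"
    out_dir: str = "mirachip_out"
    seed: int = 0
    # simulation
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_treated_samples: int = 2
    n_control_samples: int = 2
    # normalization
    loess_span: float = 0.3
    loess_iterations: int = 3
    # peak calling
    positivity_threshold: float = 1.0
    min_positive: int = 4
    max_gaps: int = 1
    max_spacing: int = 500
    # differential
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    comparisons: list[tuple[str, str]] | None = None  # (treated_id, control_id)
    # chip-mode inputs
    design_path: str | None = None
    samples: list[dict] = field(default_factory=list)  # {path, sample_id, group}
    transcripts_path: str | None = None
    transcripts_dialect: str = "bed"
    islands_path: str | None = None
    # bisulfite arm
    amplicon_fasta: str | None = None
    clone_files: dict[str, str] = field(default_factory=dict)  # group -> FASTA
    amplicon_length: int = 400
    amplicon_n_cpgs: int = 20
    n_clones: int = 50
    group_methylation: dict[str, float] = field(
        default_factory=lambda: {"treated": 0.184, "control": 0.29}
    )
    qc_min_conversion: float = 0.0  # off by default, as in the study
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        # the global seed wins over the nested simulation seed
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        if self.comparisons is not None:
            self.comparisons = [tuple(c) for c in self.comparisons]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = (
            None if self.comparisons is None else [list(c) for c in self.comparisons]
        )
        return d


@dataclass
class RunReport:
    """Provenance + per-stage counts, written as report.json."""

    mode: str
    seed: int
    version: str
    config: dict
    input_checksums: dict[str, str]
    counts: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(out_dir: Path, level: str) -> None:
    root = logging.getLogger("mirachip")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    have_file = any(isinstance(h, logging.FileHandler) for h in root.handlers)
    if not have_file:
        fh = logging.FileHandler(out_dir / "run.log", mode="a")
        fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(fh)


def _derive_annotation(design: ProbeDesign) -> tuple[list[TranscriptRecord], list[CpGIslandRecord]]:
    """Simulate-mode annotation: promoter regions become transcripts whose
    promoter window starts at the region start; CpG-island regions become
    island records."""
    transcripts, islands = [], []
    for r in design.regions:
        if r.kind == "promoter":
            tss = r.start + 2400
            transcripts.append(
                TranscriptRecord(f"{r.region_id}_tx", f"{r.region_id}_gene", r.chrom, "+", tss, tss + 1000)
            )
        else:
            islands.append(CpGIslandRecord(r.chrom, r.start, r.end, r.region_id))
    return transcripts, islands


def _load_chip_inputs(config: PipelineConfig) -> tuple[ProbeDesign, list[ArraySample], dict[str, str]]:
    if not config.design_path:
        raise ValueError("chip mode requires design_path")
    if len(config.samples) < 2:
        raise ValueError("chip mode requires at least two samples")
    checksums = {config.design_path: _sha256(Path(config.design_path))}
    design = ProbeDesign.from_probe_tsv(config.design_path)
    samples = []
    for spec in config.samples:
        path = spec["path"]
        checksums[path] = _sha256(Path(path))
        samples.append(
            read_intensities(path, design, spec["sample_id"], spec.get("group", ""))
        )
    return design, samples, checksums


def run_chip_pipeline(config: PipelineConfig) -> RunReport:
    """The array arm end-to-end. Writes, under config.out_dir:
    normalized.tsv, peaks_<sample>.bed(+.tsv), differential_<id>.tsv,
    summary.tsv, annotated.tsv, and report.json (plus design/truth/raw
    intensities in simulate mode)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    checksums: dict[str, str] = {}

    if config.mode in ("simulate", "full"):
        sim = config.simulation
        design = generate_array_design(sim)
        truth = simulate_truth_methylome(design, sim)
        design.write_probe_tsv(out / "design_probes.tsv")
        design.write_region_bed(out / "design_regions.bed")
        write_truth_json(truth, out / "truth.json")
        samples = []
        for i in range(config.n_treated_samples):
            samples.append(
                simulate_sample_intensities(design, truth, sim.treated_group, sim, f"T{i + 1}")
            )
        for i in range(config.n_control_samples):
            samples.append(
                simulate_sample_intensities(design, truth, sim.control_group, sim, f"C{i + 1}")
            )
        for s in samples:
            write_intensities(s, design, out / f"raw_{s.sample_id}.tsv")
    else:
        design, samples, checksums = _load_chip_inputs(config)

    logger.info("normalizing %d samples (%d probes)", len(samples), design.n_probes)
    samples = [
        loess_normalize(s, span=config.loess_span, iterations=config.loess_iterations)
        for s in samples
    ]
    samples = quantile_normalize(samples)
    write_normalized_tsv(samples, design, out / "normalized.tsv")

    peak_kwargs = dict(
        min_positive=config.min_positive,
        max_gaps=config.max_gaps,
        max_spacing=config.max_spacing,
    )
    sample_peaks = {}
    n_positive = {}
    for s in samples:
        from .peaks import flag_positive_probes

        n_positive[s.sample_id] = int(flag_positive_probes(s, config.positivity_threshold).sum())
        sample_peaks[s.sample_id] = call_sample_peaks(
            design, s, threshold=config.positivity_threshold, **peak_kwargs
        )
        write_peaks_bed(sample_peaks[s.sample_id], out / f"peaks_{s.sample_id}.bed")
        logger.info("sample %s: %d peaks", s.sample_id, len(sample_peaks[s.sample_id]))

    by_id = {s.sample_id: s for s in samples}
    if config.comparisons is not None:
        pairs_ids = list(config.comparisons)
    else:
        treated_ids = [s.sample_id for s in samples if s.group == config.simulation.treated_group]
        control_ids = [s.sample_id for s in samples if s.group == config.simulation.control_group]
        if not treated_ids or not control_ids:
            # fall back: first half treated, second half control
            mid = len(samples) // 2
            treated_ids = [s.sample_id for s in samples[:mid]]
            control_ids = [s.sample_id for s in samples[mid:]]
        pairs_ids = [(t, c) for t in treated_ids for c in control_ids]

    pairs = []
    for t_id, c_id in pairs_ids:
        if t_id not in by_id or c_id not in by_id:
            raise ValueError(f"comparison ({t_id}, {c_id}) references unknown sample")
        pairs.append((by_id[t_id], by_id[c_id], sample_peaks[t_id], sample_peaks[c_id]))
    summaries = summarize_comparisons(pairs, design=design, delta_threshold=config.delta_threshold)
    for s in summaries:
        calls_table(s).to_csv(out / f"differential_{s.comparison_id}.tsv", sep="\t",
                              index=False, float_format="%.6f")
    summary_table(summaries).to_csv(out / "summary.tsv", sep="\t", index=False)

    if config.transcripts_path:
        checksums[config.transcripts_path] = _sha256(Path(config.transcripts_path))
        transcripts = read_transcript_table(config.transcripts_path, config.transcripts_dialect)
    else:
        transcripts = None
    if config.islands_path:
        checksums[config.islands_path] = _sha256(Path(config.islands_path))
        islands = read_cpg_islands(config.islands_path)
    else:
        islands = None
    if transcripts is None and islands is None:
        transcripts, islands = _derive_annotation(design)
    all_calls = [c.peak for s in summaries for c in s.calls]
    annotated = annotate_peaks(all_calls, transcripts or [], islands or [])
    annotation_table(annotated).to_csv(out / "annotated.tsv", sep="\t", index=False)

    report = RunReport(
        mode=config.mode,
        seed=config.seed,
        version=__version__,
        config=config.to_dict(),
        input_checksums=checksums,
        counts={
            "n_probes": design.n_probes,
            "n_regions": len(design.regions),
            "n_samples": len(samples),
            "positive_probes": n_positive,
            "peaks_per_sample": {k: len(v) for k, v in sample_peaks.items()},
            "differential_calls": {s.comparison_id: s.n_calls for s in summaries},
            "n_hyper": {s.comparison_id: s.n_hyper for s in summaries},
            "n_hypo": {s.comparison_id: s.n_hypo for s in summaries},
            "annotated_calls": len(annotated),
        },
    )
    report.write(out / "report.json")
    return report


def run_bisulfite_report(config: PipelineConfig) -> RunReport:
    """The verification arm: COBRA site report, per-group methylation
    matrices, lollipop diagrams, and a percent-methylation comparison
    table. In simulate mode clones are drawn from group_methylation."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    checksums: dict[str, str] = {}

    if not config.amplicon_fasta:
        if config.clone_files:
            raise ValueError("clone_files given without amplicon_fasta")
        amplicons = [
            generate_amplicon(
                "ampliconA",
                length=config.amplicon_length,
                n_cpgs=config.amplicon_n_cpgs,
                seed=config.seed,
            )
        ]
        group_clones: dict[str, list[tuple[str, str]]] = {}
        import zlib

        for group, prob in config.group_methylation.items():
            probs = np.full(amplicons[0].n_cpgs, float(prob))
            group_seed = (config.seed + zlib.crc32(group.encode())) % (2**31 - 1)
            clones, _truth = simulate_bisulfite_clones(
                amplicons[0], probs, config.n_clones,
                dataclasses.replace(config.simulation, seed=group_seed),
            )
            clones = [(f"{group}_{cid}", seq) for cid, seq in clones]
            group_clones[group] = clones
            write_clone_fasta(clones, out / f"clones_{group}.fasta")
    else:
        if not config.amplicon_fasta:
            raise ValueError("bisulfite mode requires amplicon_fasta (or simulate mode)")
        checksums[config.amplicon_fasta] = _sha256(Path(config.amplicon_fasta))
        amplicons = Amplicon.from_fasta(config.amplicon_fasta)
        if not config.clone_files:
            raise ValueError("bisulfite mode requires clone_files (group -> FASTA)")
        group_clones = {}
        for group, path in config.clone_files.items():
            checksums[path] = _sha256(Path(path))
            group_clones[group] = read_clone_fasta(path)

    # COBRA expectations per amplicon
    cobra_rows = []
    for amp in amplicons:
        rep = cobra_site_analysis(amp)
        cobra_rows.append(
            {
                "amplicon": amp.name,
                "length": rep.amplicon_length,
                "enzyme": rep.enzyme_motif,
                "n_sites": len(rep.sites),
                "site_positions": ";".join(str(s.position) for s in rep.sites),
                "fragments_fully_methylated": ";".join(map(str, rep.fragments_methylated)),
                "fragments_fully_unmethylated": ";".join(map(str, rep.fragments_unmethylated)),
                "verdict": rep.verdict,
            }
        )
    import pandas as pd

    pd.DataFrame(cobra_rows).to_csv(out / "cobra_report.tsv", sep="\t", index=False)

    pct_rows = []
    n_fail = 0
    for group, clones in group_clones.items():
        for amp in amplicons:
            calls = []
            for clone_id, seq in clones:
                try:
                    calls.append(align_and_call_clone(seq, amp, clone_id=clone_id))
                except CloneAlignmentError as exc:
                    logger.warning("%s", exc)
                    n_fail += 1
            if not calls:
                continue
            matrix = MethylationMatrix(amplicon=amp, clones=calls)
            qc_only = config.qc_min_conversion > 0
            pct = percent_methylation(
                matrix, qc_only=qc_only, min_conversion=config.qc_min_conversion
            )
            tag = f"{amp.name}_{group}"
            (out / f"lollipop_{tag}.txt").write_text(render_lollipop(matrix))
            mat = pd.DataFrame(
                matrix.to_array(),
                index=[c.clone_id for c in calls],
                columns=[f"CpG_{p}" for p in amp.cpg_positions],
            )
            mat.to_csv(out / f"matrix_{tag}.tsv", sep="\t")
            pct_rows.append(
                {
                    "amplicon": amp.name,
                    "group": group,
                    "n_clones": len(calls),
                    "percent_methylated": round(pct, 1),
                }
            )
    if not pct_rows:
        raise ValueError("no clones aligned to any amplicon; nothing to report")
    pct_df = pd.DataFrame(pct_rows).sort_values(["amplicon", "group"]).reset_index(drop=True)
    pct_df.to_csv(out / "percent_methylation.tsv", sep="\t", index=False)

    report = RunReport(
        mode=config.mode,
        seed=config.seed,
        version=__version__,
        config=config.to_dict(),
        input_checksums=checksums,
        counts={
            "n_amplicons": len(amplicons),
            "clones_per_group": {g: len(c) for g, c in group_clones.items()},
            "unalignable_clones": n_fail,
            "percent_methylated": {
                f"{r['amplicon']}_{r['group']}": r["percent_methylated"] for r in pct_rows
            },
        },
    )
    report.write(out / "bisulfite_report.json")
    return report
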