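"""Bisulfite-based verification: in-silico conversion, COBRA restriction
scoring, clone-to-amplicon methylation calling, and lollipop rendering.

Bisulfite chemistry converts unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine resists. Only the top (sense)
strand of the amplicon is modeled; reverse-complement clone reads are
flipped back before calling. Clones are PCR products of a fixed amplicon,
so a gapless alignment suffices — indel-containing reads fail QC rather
than being realigned.

Per-CpG call codes: 1 methylated, 0 unmethylated, -1 missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Amplicon",
    "CloneCall",
    "MethylationMatrix",
    "CobraSite",
    "CobraReport",
    "CloneAlignmentError",
    "METHYLATED",
    "UNMETHYLATED",
    "MISSING",
    "bisulfite_convert",
    "cobra_site_analysis",
    "align_and_call_clone",
    "clone_qc",
    "percent_methylation",
    "render_lollipop",
    "render_lollipop_figure",
]

METHYLATED = 1
UNMETHYLATED = 0
MISSING = -1

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: mismatch fraction above which no alignment is accepted at all
HARD_ALIGN_LIMIT = 0.3


class CloneAlignmentError(ValueError):
    """Raised when no orientation/offset of a clone read aligns to the
    bisulfite-converted reference frame."""


def _find_cpg_positions(sequence: str) -> list[int]:
    return [m.start() for m in re.finditer("(?=CG)", sequence)]


@dataclass
class Amplicon:
    """A bisulfite PCR target: genomic top-strand sequence + its CpG map."""

    name: str
    sequence: str
    cpg_positions: list[int] = field(default_factory=list)
    enzyme_sites: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"amplicon {self.name}: non-ACGT characters {bad}")
        true_positions = _find_cpg_positions(self.sequence)
        if self.cpg_positions:
            if list(self.cpg_positions) != true_positions:
                raise ValueError(f"amplicon {self.name}: cpg_positions do not match sequence")
        else:
            self.cpg_positions = true_positions

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @classmethod
    def from_fasta(cls, path: str | Path) -> list["Amplicon"]:
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return [cls(name=r.id, sequence=str(r.seq)) for r in records]


@dataclass
class CloneCall:
    """Per-CpG methylation vector for one sequenced clone."""

    clone_id: str
    per_cpg: np.ndarray  # int8 codes over {METHYLATED, UNMETHYLATED, MISSING}
    conversion_efficiency: float
    pass_qc: bool
    mismatch_frac: float = 0.0
    orientation: str = "forward"
    offset: int = 0

    def __post_init__(self) -> None:
        self.per_cpg = np.asarray(self.per_cpg, dtype=np.int8)

    @property
    def n_methylated(self) -> int:
        return int(np.sum(self.per_cpg == METHYLATED))

    @property
    def n_unmethylated(self) -> int:
        return int(np.sum(self.per_cpg == UNMETHYLATED))


@dataclass
class MethylationMatrix:
    """Clones x CpGs methylation calls for one amplicon."""

    amplicon: Amplicon
    clones: list[CloneCall]

    def __post_init__(self) -> None:
        for c in self.clones:
            if c.per_cpg.size != self.amplicon.n_cpgs:
                raise ValueError(
                    f"clone {c.clone_id}: {c.per_cpg.size} calls for "
                    f"{self.amplicon.n_cpgs} CpGs"
                )

    @property
    def percent_methylated(self) -> float:
        return percent_methylation(self, qc_only=False)

    def to_array(self) -> np.ndarray:
        if not self.clones:
            return np.zeros((0, self.amplicon.n_cpgs), dtype=np.int8)
        return np.vstack([c.per_cpg for c in self.clones])


def bisulfite_convert(
    sequence: str,
    methylated_positions: Iterable[int],
    conversion_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Convert every cytosine outside `methylated_positions` to thymine with
    probability `conversion_rate` (deterministic at 1.0).

    `methylated_positions` must be CpG cytosine positions of `sequence`;
    methylated Cs and all non-C bases are untouched. Conversion failures
    (rate < 1) can strike any unmethylated C, including CpG Cs, which is how
    real incomplete conversion produces spurious methylation calls.
    """
    if not 0.0 <= conversion_rate <= 1.0:
        raise ValueError("conversion_rate must lie in [0, 1]")
    seq = sequence.upper()
    cpg = set(_find_cpg_positions(seq))
    methylated = set(int(p) for p in methylated_positions)
    bad = methylated - cpg
    if bad:
        raise ValueError(f"methylated positions {sorted(bad)} are not CpG cytosines")
    if conversion_rate < 1.0 and rng is None:
        rng = np.random.default_rng(seed)
    out = list(seq)
    for i, base in enumerate(out):
        if base != "C" or i in methylated:
            continue
        if conversion_rate >= 1.0 or rng.random() < conversion_rate:
            out[i] = "T"
    return "".join(out)


@dataclass(frozen=True)
class CobraSite:
    """One restriction-site occurrence and its methylation dependence."""

    position: int  # 0-based start of the motif
    motif: str
    cpg_position: int  # 0-based position of the site's CpG cytosine
    retained_if_methylated: bool = True
    retained: bool | None = None  # given an explicit methylation state


@dataclass
class CobraReport:
    amplicon_name: str
    amplicon_length: int
    enzyme_motif: str
    sites: list[CobraSite]
    fragments_methylated: list[int]  # fully methylated digest
    fragments_unmethylated: list[int]  # fully unmethylated: uncut
    fragments_observed: list[int] | None = None  # for a supplied state
    verdict: str = ""


def _digest_fragments(length: int, cut_positions: Sequence[int]) -> list[int]:
    cuts = sorted(set(int(c) for c in cut_positions))
    bounds = [0] + cuts + [length]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def cobra_site_analysis(
    amplicon: Amplicon,
    enzyme_motif: str = "TCGA",
    methylated_positions: Iterable[int] | None = None,
) -> CobraReport:
    """Score COBRA (combined bisulfite restriction analysis) for one enzyme.

    A site survives bisulfite conversion — and stays cleavable after PCR —
    only if its CpG is methylated (unmethylated TCGA reads TTGA). Expected
    fragment sizes are reported for the fully methylated digest, the fully
    unmethylated case (uncut, one full-length fragment), and optionally for
    an explicit methylation state. The enzyme is assumed to cut immediately
    before the motif's CpG (TaqαI: T^CGA).
    """
    motif = enzyme_motif.upper()
    if motif.count("CG") != 1:
        raise ValueError(f"enzyme motif {motif!r} must contain exactly one CpG")
    cg_offset = motif.index("CG")
    length = len(amplicon.sequence)
    meth = None if methylated_positions is None else set(int(p) for p in methylated_positions)

    sites = []
    for m in re.finditer(f"(?={re.escape(motif)})", amplicon.sequence):
        pos = m.start()
        cpg_pos = pos + cg_offset
        retained = None if meth is None else (cpg_pos in meth)
        sites.append(CobraSite(pos, motif, cpg_pos, True, retained))

    all_cuts = [s.position + cg_offset for s in sites]
    report = CobraReport(
        amplicon_name=amplicon.name,
        amplicon_length=length,
        enzyme_motif=motif,
        sites=sites,
        fragments_methylated=_digest_fragments(length, all_cuts),
        fragments_unmethylated=[length],
        verdict="uncut" if not sites else "methylation-dependent cleavage",
    )
    if meth is not None:
        observed_cuts = [s.position + cg_offset for s in sites if s.retained]
        report.fragments_observed = _digest_fragments(length, observed_cuts)
    amplicon.enzyme_sites = [(s.position, motif) for s in sites]
    return report


def _converted_reference(amplicon: Amplicon) -> str:
    """Reference frame after conversion with every CpG methylated: non-CpG
    Cs read T, CpG Cs stay ambiguous (C if methylated, T if not)."""
    return bisulfite_convert(amplicon.sequence, amplicon.cpg_positions, conversion_rate=1.0)


def _score_alignment(read: str, ref: str, amplicon: Amplicon, offset: int) -> int:
    """Count positions not explainable by bisulfite chemistry."""
    mismatches = 0
    cpg = set(amplicon.cpg_positions)
    for i, base in enumerate(read):
        p = offset + i
        ref_base = amplicon.sequence[p]
        if ref_base == "C":
            ok = base in ("C", "T")
        else:
            ok = base == ref_base
        if not ok:
            mismatches += 1
    return mismatches


def align_and_call_clone(
    clone_read: str,
    amplicon: Amplicon,
    max_mismatch_frac: float = 0.1,
    clone_id: str = "clone",
) -> CloneCall:
    """Gapless alignment of a clone read to the bisulfite-converted frame of
    its amplicon, then per-CpG calling: C → methylated, T → unmethylated,
    anything else → missing.

    Both orientations are tried (reverse-complement reads are flipped back);
    for reads shorter than the amplicon every offset is scanned and the one
    with the fewest chemistry-inexplicable mismatches wins. A clone whose
    best mismatch fraction exceeds `max_mismatch_frac` is kept but flagged
    pass_qc=False; above a hard limit (0.3) no alignment is accepted and a
    CloneAlignmentError is raised.

    conversion_efficiency is the fraction of covered non-CpG cytosines that
    read as T (i.e. were converted).
    """
    read = clone_read.upper()
    L = len(amplicon.sequence)
    if not read or len(read) > L:
        raise CloneAlignmentError(f"clone {clone_id}: read empty or longer than amplicon")
    ref = _converted_reference(amplicon)

    best = None  # (mismatches, orientation, offset, oriented_read)
    for orientation, oriented in (
        ("forward", read),
        ("reverse", read.translate(_COMPLEMENT)[::-1]),
    ):
        for offset in range(L - len(read) + 1):
            mm = _score_alignment(oriented, ref, amplicon, offset)
            if best is None or mm < best[0]:
                best = (mm, orientation, offset, oriented)
    mismatches, orientation, offset, oriented = best
    frac = mismatches / len(read)
    if frac > HARD_ALIGN_LIMIT:
        raise CloneAlignmentError(
            f"clone {clone_id}: best alignment has mismatch fraction "
            f"{frac:.2f} (> {HARD_ALIGN_LIMIT}); read does not match amplicon "
            f"{amplicon.name}"
        )

    span = range(offset, offset + len(oriented))
    cpg = set(amplicon.cpg_positions)
    calls = np.full(amplicon.n_cpgs, MISSING, dtype=np.int8)
    for k, p in enumerate(amplicon.cpg_positions):
        if p not in span:
            continue
        base = oriented[p - offset]
        if base == "C":
            calls[k] = METHYLATED
        elif base == "T":
            calls[k] = UNMETHYLATED
    converted = unconverted = 0
    for p in span:
        if amplicon.sequence[p] == "C" and p not in cpg:
            base = oriented[p - offset]
            if base == "T":
                converted += 1
            elif base == "C":
                unconverted += 1
    denom = converted + unconverted
    efficiency = converted / denom if denom else 1.0
    return CloneCall(
        clone_id=clone_id,
        per_cpg=calls,
        conversion_efficiency=efficiency,
        pass_qc=frac <= max_mismatch_frac,
        mismatch_frac=frac,
        orientation=orientation,
        offset=offset,
    )


def clone_qc(call: CloneCall, min_conversion: float = 0.95) -> bool:
    """Pass iff the alignment QC passed and conversion efficiency reaches
    `min_conversion`. The study this mirrors applied no conversion filter,
    so set min_conversion=0 (or qc_only=False downstream) to include all
    aligned clones."""
    return bool(call.pass_qc and call.conversion_efficiency >= min_conversion)


def percent_methylation(
    matrix: MethylationMatrix, qc_only: bool = True, min_conversion: float = 0.95
) -> float:
    """100 x methylated / (methylated + unmethylated) over the included
    clones; missing calls are excluded from both counts."""
    clones = [
        c for c in matrix.clones if not qc_only or clone_qc(c, min_conversion=min_conversion)
    ]
    if not clones:
        raise ValueError(f"amplicon {matrix.amplicon.name}: no clones pass QC")
    meth = sum(c.n_methylated for c in clones)
    unmeth = sum(c.n_unmethylated for c in clones)
    if meth + unmeth == 0:
        raise ValueError(f"amplicon {matrix.amplicon.name}: zero callable CpG sites")
    return 100.0 * meth / (meth + unmeth)


_GLYPHS = {METHYLATED: "●", UNMETHYLATED: "○", MISSING: "·"}


def render_lollipop(matrix: MethylationMatrix, qc_only: bool = False) -> str:
    """Text lollipop diagram: one row per clone, one column per CpG in
    genomic order; filled circle methylated, open circle unmethylated,
    middle dot missing. The overall percent methylation is printed below."""
    lines = [f"# {matrix.amplicon.name}: {matrix.amplicon.n_cpgs} CpG sites"]
    if not matrix.clones:
        lines.append("(no clones)")
        return "\n".join(lines) + "\n"
    width = max(len(c.clone_id) for c in matrix.clones)
    for c in matrix.clones:
        row = "".join(_GLYPHS[int(v)] for v in c.per_cpg)
        lines.append(f"{c.clone_id:<{width}}  {row}")
    pct = percent_methylation(matrix, qc_only=qc_only)
    lines.append(f"{pct:.1f}% methylated ({len(matrix.clones)} clones)")
    return "\n".join(lines) + "\n"


def render_lollipop_figure(matrix: MethylationMatrix, path: str | Path):
    """Graphical lollipop plot (one marker per clone x CpG) saved to
    `path` if given; returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_clones, n_cpgs = len(matrix.clones), matrix.amplicon.n_cpgs
    fig, ax = plt.subplots(figsize=(max(2, 0.25 * n_cpgs), max(1.5, 0.25 * n_clones)))
    for row, clone in enumerate(matrix.clones):
        y = n_clones - 1 - row
        for col, v in enumerate(clone.per_cpg):
            if v == MISSING:
                ax.plot(col, y, marker=".", color="grey", markersize=3)
            else:
                filled = v == METHYLATED
                ax.plot(
                    col, y, marker="o", markersize=7,
                    markerfacecolor="black" if filled else "white",
                    markeredgecolor="black",
                )
    ax.set_xlim(-0.5, n_cpgs - 0.5)
    ax.set_ylim(-0.5, n_clones - 0.5 if n_clones else 0.5)
    ax.set_xticks(range(n_cpgs))
    ax.set_xticklabels([str(p) for p in matrix.amplicon.cpg_positions], rotation=90, fontsize=6)
    ax.set_yticks([])
    pct = percent_methylation(matrix, qc_only=False) if matrix.clones else float("nan")
    ax.set_title(f"{matrix.amplicon.name}: {pct:.1f}% methylated", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
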