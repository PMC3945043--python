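"""Synthetic GRO-seq data with known ground truth.

The generator emulates the statistical structure of nascent-transcription
data: strand-specific background noise, transcription units with
promoter-proximal pausing peaks at their 5' ends, short divergent eRNA
pairs in intergenic space, short highly-expressed non-Pol II (Pol I/III)
units, and an alpha-amanitin condition in which Pol II unit expression is
multiplied by a suppression factor while non-Pol II units and background
are untouched.  Per-bin counts are Poisson unless a dispersion knob makes
them negative binomial.  Every element is recorded in a TruthSet so each
pipeline stage can be scored against what was planted.

All planted coordinates are aligned to the bin grid, and distinct elements
keep a configurable minimum genomic spacing (default 2 kb) so that planted
functional classes are unambiguous by construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, ChromSizes, GenomicInterval
from .hmm import TranscriptUnit
from . import io as nsio


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome; defaults define the study conditions.

    ``background_rate`` is the expected reads per bin outside units;
    expression values are the additional per-bin Poisson mean inside a
    unit.  ``amanitin_pol2_suppression`` is the factor applied to Pol II
    unit expression in the alpha-amanitin condition (0.05 means 95%
    inhibition).  Lengths are in bp and snap to the bin grid.
    """

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chrS1": 5_000_000, "chrS2": 5_000_000}
    )
    bin_width: int = 25
    # protein-coding genes (Pol II units)
    n_genes: int = 200
    gene_length_meanlog: float = math.log(5000.0)
    gene_length_sdlog: float = 0.45
    gene_length_range: Tuple[int, int] = (1500, 40_000)
    # per-bin expression (log-normal, clamped below)
    expression_meanlog: float = math.log(10.0)
    expression_sdlog: float = 0.5
    expression_min: float = 5.0
    background_rate: float = 0.25
    dispersion: float = 0.0  # >0: negative-binomial bin counts, var = m + d*m^2
    # promoter-proximal pausing
    pause_factor: float = 5.0
    k_pause: int = 2  # bins
    # other planted element classes
    n_lncrna: int = 10
    lncrna_length_range: Tuple[int, int] = (2000, 8000)
    n_divergent: int = 10
    n_antisense: int = 10
    n_repeat: int = 5
    repeat_length_range: Tuple[int, int] = (1000, 3000)
    n_other_genic: int = 5
    n_intergenic: int = 10
    intergenic_length_range: Tuple[int, int] = (1000, 4000)
    # eRNA pairs
    n_erna_pairs: int = 20
    erna_length_range: Tuple[int, int] = (500, 2000)
    erna_overlap_halfwidth: int = 100
    nfkb_fraction: float = 0.5
    nfkb_peak_width: int = 200
    # non-Pol II (Pol I/III) units
    n_non_pol2: int = 30
    non_pol2_length_range: Tuple[int, int] = (100, 400)
    non_pol2_expression: float = 20.0
    amanitin_pol2_suppression: float = 0.05
    # reads
    read_length_range: Tuple[int, int] = (33, 100)
    min_gap: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.amanitin_pol2_suppression <= 1):
            raise ValueError("amanitin_pol2_suppression must lie in [0, 1]")
        if self.background_rate < 0 or self.expression_min < 0:
            raise ValueError("rates must be non-negative")
        if self.read_length_range[0] < 33:
            raise ValueError("minimum read length is 33 bp")
        if self.erna_length_range[1] >= 9000:
            raise ValueError("eRNA unit lengths must stay below 9 kb")

    @classmethod
    def caller_benchmark(cls, **kwargs) -> "SimulationConfig":
        """10-Mb genome with 200 plain transcription units and nothing else:
        the transcript-caller benchmark condition."""
        kwargs.setdefault("n_genes", 200)
        for knob in ("n_lncrna", "n_divergent", "n_antisense", "n_repeat",
                     "n_other_genic", "n_intergenic", "n_erna_pairs",
                     "n_non_pol2"):
            kwargs.setdefault(knob, 0)
        return cls(**kwargs)


@dataclass
class TruthUnit:
    """One planted transcription unit with its ground-truth labels."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str
    cls: str  # planted functional class
    expression: float  # per-bin Poisson mean on top of background; 0 = silent
    polymerase: str  # pol2 | non_pol2
    pair_id: Optional[str] = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.id)

    def as_transcript_unit(self) -> TranscriptUnit:
        return TranscriptUnit(self.interval, self.expression, self.id)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TruthPair:
    pair_id: str
    chrom: str
    center: int
    nfkb: bool
    plus_id: str
    minus_id: str


@dataclass
class TruthSet:
    units: List[TruthUnit] = field(default_factory=list)
    pairs: List[TruthPair] = field(default_factory=list)

    def expressed_units(self) -> List[TruthUnit]:
        return [u for u in self.units if u.expression > 0]

    def to_frame(self) -> pd.DataFrame:
        pair_info = {p.pair_id: p for p in self.pairs}
        rows = []
        for u in self.units:
            p = pair_info.get(u.pair_id)
            rows.append({
                "chrom": u.chrom, "start": u.start, "end": u.end,
                "strand": u.strand, "id": u.id, "class": u.cls,
                "expression": u.expression, "polymerase": u.polymerase,
                "pair_id": u.pair_id or ".",
                "pair_center": p.center if p else -1,
                "nfkb": int(p.nfkb) if p else -1,
            })
        return pd.DataFrame(rows)


@dataclass
class SimulationResult:
    config: SimulationConfig
    sizes: ChromSizes
    reads: Dict[str, List[GenomicInterval]]  # condition -> reads
    annotations: AnnotationSet
    repeats: List[GenomicInterval]
    peaks: List[GenomicInterval]
    truth: TruthSet

    def write(self, outdir) -> Dict[str, Path]:
        """Write the standard pipeline input files; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        for cond, reads in self.reads.items():
            p = outdir / f"reads_{cond}.bed"
            nsio.write_bed(reads, p)
            paths[f"reads_{cond}"] = p
        p = outdir / "genes.gtf"
        _write_gtf(self.annotations, p)
        paths["genes"] = p
        for name, ivs in (("rmsk", self.repeats), ("peaks", self.peaks)):
            p = outdir / f"{name}.bed"
            nsio.write_bed(ivs, p)
            paths[name] = p
        p = outdir / "sizes.tsv"
        nsio.write_chrom_sizes(self.sizes, p)
        paths["sizes"] = p
        p = outdir / "truth.tsv"
        self.truth.to_frame().to_csv(p, sep="\t", index=False)
        paths["truth"] = p
        return paths


_CATEGORY_TO_BIOTYPE = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "short_ncRNA:tRNA": "tRNA",
    "short_ncRNA:rRNA": "rRNA",
    "short_ncRNA:snRNA": "snRNA",
    "short_ncRNA:miRNA": "miRNA",
}


def _write_gtf(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for gene, cat in ann:
            biotype = _CATEGORY_TO_BIOTYPE.get(cat, cat)
            attrs = (
                f'gene_id "{gene.name}"; transcript_id "{gene.name}"; '
                f'gene_biotype "{biotype}";'
            )
            fh.write(
                f"{gene.chrom}\tsim\ttranscript\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )


class _Placer:
    """Sequentially allocates non-overlapping, bin-aligned territories."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.cursors = {c: cfg.bin_width for c in sorted(cfg.chrom_lengths)}
        self.order = sorted(cfg.chrom_lengths)
        self.next_chrom = 0

    def place(self, span: int) -> Tuple[str, int]:
        """Reserve ``span`` bp somewhere; returns (chrom, start)."""
        bw = self.cfg.bin_width
        gap = int(self.cfg.min_gap + self.rng.integers(0, 3 * self.cfg.min_gap))
        gap = -(-gap // bw) * bw
        for _ in range(len(self.order)):
            chrom = self.order[self.next_chrom % len(self.order)]
            self.next_chrom += 1
            start = self.cursors[chrom] + gap
            if start + span + bw < self.cfg.chrom_lengths[chrom]:
                self.cursors[chrom] = start + span
                return chrom, start
        raise RuntimeError(
            "simulated genome too small for the requested elements"
        )


def _snap(x: float, bw: int, lo: int, hi: int) -> int:
    v = int(round(x / bw)) * bw
    return int(min(max(v, -(-lo // bw) * bw), (hi // bw) * bw))


def simulate(config: Optional[SimulationConfig] = None) -> SimulationResult:
    """Generate a synthetic dataset; fully determined by ``config.seed``."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    bw = cfg.bin_width
    placer = _Placer(cfg, rng)
    truth = TruthSet()
    ann = AnnotationSet()
    repeats: List[GenomicInterval] = []
    peaks: List[GenomicInterval] = []

    def draw_length(meanlog, sdlog, lo, hi):
        return _snap(float(rng.lognormal(meanlog, sdlog)), bw, lo, hi)

    def draw_uniform_length(lo, hi):
        return _snap(float(rng.integers(lo, hi + 1)), bw, lo, hi)

    def draw_expression():
        return max(cfg.expression_min, float(rng.lognormal(
            cfg.expression_meanlog, cfg.expression_sdlog)))

    def rand_strand() -> str:
        return "+" if rng.integers(0, 2) == 0 else "-"

    serial = {"gene": 0, "lnc": 0, "div": 0, "as": 0, "rep": 0, "og": 0,
              "ig": 0, "erna": 0, "np2": 0}

    def next_id(kind: str) -> str:
        serial[kind] += 1
        return f"{kind}_{serial[kind]:04d}"

    # ---- protein-coding genes -------------------------------------------
    for _ in range(cfg.n_genes):
        L = draw_length(cfg.gene_length_meanlog, cfg.gene_length_sdlog,
                        *cfg.gene_length_range)
        chrom, t = placer.place(L)
        strand = rand_strand()
        gid = next_id("gene")
        ann.add(GenomicInterval(chrom, t, t + L, strand, gid), "protein_coding")
        truth.units.append(TruthUnit(chrom, t, t + L, strand, gid,
                                     "protein_coding", draw_expression(), "pol2"))

    # ---- lncRNAs ---------------------------------------------------------
    for _ in range(cfg.n_lncrna):
        L = draw_uniform_length(*cfg.lncrna_length_range)
        chrom, t = placer.place(L)
        strand = rand_strand()
        gid = next_id("lnc")
        ann.add(GenomicInterval(chrom, t, t + L, strand, gid), "lncRNA")
        truth.units.append(TruthUnit(chrom, t, t + L, strand, gid,
                                     "non_coding", draw_expression(), "pol2"))

    # ---- divergent transcripts at gene promoters ------------------------
    for _ in range(cfg.n_divergent):
        Lg = draw_length(cfg.gene_length_meanlog, cfg.gene_length_sdlog,
                         max(3000, cfg.gene_length_range[0]),
                         cfg.gene_length_range[1])
        Ld = 500  # divergent unit length; < 50% of any primary >= 3 kb
        chrom, t = placer.place(Lg + Ld)
        strand = rand_strand()
        gid, did = next_id("gene"), next_id("div")
        if strand == "+":
            g0, g1 = t + Ld, t + Ld + Lg      # gene body; TSS at g0
            d0, d1 = t, t + Ld                 # divergent unit, upstream antisense
            dstrand = "-"
        else:
            g0, g1 = t, t + Lg                 # TSS at g1 - 1
            d0, d1 = t + Lg, t + Lg + Ld
            dstrand = "+"
        ann.add(GenomicInterval(chrom, g0, g1, strand, gid), "protein_coding")
        truth.units.append(TruthUnit(chrom, g0, g1, strand, gid,
                                     "protein_coding", draw_expression(), "pol2"))
        truth.units.append(TruthUnit(chrom, d0, d1, dstrand, did,
                                     "divergent", draw_expression(), "pol2"))

    # ---- antisense units inside gene bodies ------------------------------
    for _ in range(cfg.n_antisense):
        Lg = draw_length(cfg.gene_length_meanlog, cfg.gene_length_sdlog,
                         max(4000, cfg.gene_length_range[0]),
                         cfg.gene_length_range[1])
        chrom, t = placer.place(Lg)
        strand = rand_strand()
        gid, aid = next_id("gene"), next_id("as")
        ann.add(GenomicInterval(chrom, t, t + Lg, strand, gid), "protein_coding")
        truth.units.append(TruthUnit(chrom, t, t + Lg, strand, gid,
                                     "protein_coding", draw_expression(), "pol2"))
        a0 = _snap(t + 0.3 * Lg, bw, t, t + Lg)
        a1 = _snap(t + 0.7 * Lg, bw, t, t + Lg)
        astrand = "-" if strand == "+" else "+"
        truth.units.append(TruthUnit(chrom, a0, a1, astrand, aid,
                                     "antisense", draw_expression(), "pol2"))

    # ---- repeat-region units ---------------------------------------------
    for _ in range(cfg.n_repeat):
        L = draw_uniform_length(*cfg.repeat_length_range)
        chrom, t = placer.place(L)
        rid = next_id("rep")
        repeats.append(GenomicInterval(chrom, t, t + L, ".", f"rmsk_{rid}"))
        truth.units.append(TruthUnit(chrom, t, t + L, rand_strand(), rid,
                                     "repeat", draw_expression(), "pol2"))

    # ---- other-genic: unit hanging off a silent gene's 3' end (10% in) ---
    for _ in range(cfg.n_other_genic):
        Lg = draw_length(cfg.gene_length_meanlog, cfg.gene_length_sdlog,
                         max(3000, cfg.gene_length_range[0]),
                         cfg.gene_length_range[1])
        Lu = 2000
        overlap = 200  # 10% of the unit inside the annotation
        chrom, t = placer.place(Lg + Lu - overlap)
        gid, oid = next_id("gene"), next_id("og")
        ann.add(GenomicInterval(chrom, t, t + Lg, "+", gid), "protein_coding")
        truth.units.append(TruthUnit(chrom, t + Lg - overlap, t + Lg - overlap + Lu,
                                     "+", oid, "other_genic",
                                     draw_expression(), "pol2"))

    # ---- isolated intergenic units ---------------------------------------
    for _ in range(cfg.n_intergenic):
        L = draw_uniform_length(*cfg.intergenic_length_range)
        chrom, t = placer.place(L)
        truth.units.append(TruthUnit(chrom, t, t + L, rand_strand(),
                                     next_id("ig"), "intergenic",
                                     draw_expression(), "pol2"))

    # ---- eRNA pairs ------------------------------------------------------
    w = _snap(cfg.erna_overlap_halfwidth, bw, bw, 10 * bw)
    for _ in range(cfg.n_erna_pairs):
        Lp = draw_uniform_length(*cfg.erna_length_range)
        # keep the pair size-balanced so neither member reads as a
        # divergent partner of the other (size ratio within [0.6, 1.67])
        Lm = _snap(Lp * float(rng.uniform(0.75, 1.33)), bw,
                   max(cfg.erna_length_range[0], 2 * w),
                   cfg.erna_length_range[1])
        Lp = max(Lp, 2 * w)
        span = Lp + Lm - 2 * w
        chrom, t = placer.place(span)
        c = t + Lm - w
        pid = next_id("erna")
        plus_id, minus_id = f"{pid}_p", f"{pid}_m"
        expr = draw_expression()
        truth.units.append(TruthUnit(chrom, c - w, c - w + Lp, "+", plus_id,
                                     "eRNA", expr, "pol2", pair_id=pid))
        truth.units.append(TruthUnit(chrom, c + w - Lm, c + w, "-", minus_id,
                                     "eRNA", expr, "pol2", pair_id=pid))
        nfkb = bool(rng.random() < cfg.nfkb_fraction)
        truth.pairs.append(TruthPair(pid, chrom, c, nfkb, plus_id, minus_id))
        if nfkb:
            delta = int(rng.integers(-500, 501))
            half = cfg.nfkb_peak_width // 2
            pc = c + delta
            peaks.append(GenomicInterval(chrom, max(0, pc - half), pc + half,
                                         ".", f"peak_{pid}"))

    # ---- non-Pol II (Pol I/III) units ------------------------------------
    for _ in range(cfg.n_non_pol2):
        L = max(bw, draw_uniform_length(*cfg.non_pol2_length_range))
        chrom, t = placer.place(L)
        strand = rand_strand()
        nid = next_id("np2")
        ann.add(GenomicInterval(chrom, t, t + L, strand, nid), "short_ncRNA:tRNA")
        truth.units.append(TruthUnit(chrom, t, t + L, strand, nid,
                                     "non_coding", cfg.non_pol2_expression,
                                     "non_pol2"))

    sizes = ChromSizes(dict(cfg.chrom_lengths))
    reads = {
        cond: _materialize_reads(cfg, truth, rng, condition=cond)
        for cond in ("control", "amanitin")
    }
    return SimulationResult(cfg, sizes, reads, ann, repeats, peaks, truth)


def _rate_vectors(cfg: SimulationConfig, truth: TruthSet,
                  condition: str) -> Dict[Tuple[str, str], np.ndarray]:
    """Per-(chrom, strand) expected reads per bin."""
    bw = cfg.bin_width
    lam: Dict[Tuple[str, str], np.ndarray] = {}
    for chrom, length in sorted(cfg.chrom_lengths.items()):
        n_bins = -(-length // bw)
        for strand in ("+", "-"):
            lam[(chrom, strand)] = np.full(n_bins, cfg.background_rate)
    for u in truth.units:
        expr = u.expression
        if condition == "amanitin" and u.polymerase == "pol2":
            expr *= cfg.amanitin_pol2_suppression
        if expr <= 0:
            continue
        vec = lam[(u.chrom, u.strand)]
        b0, b1 = u.start // bw, u.end // bw
        vec[b0:b1] += expr
        k = min(cfg.k_pause, b1 - b0)
        boost = expr * (cfg.pause_factor - 1)
        if u.strand == "+":
            vec[b0:b0 + k] += boost  # 5' pausing peak
        else:
            vec[b1 - k:b1] += boost
    return lam


def _materialize_reads(cfg: SimulationConfig, truth: TruthSet,
                       rng: np.random.Generator, condition: str
                       ) -> List[GenomicInterval]:
    bw = cfg.bin_width
    lmin, lmax = cfg.read_length_range
    reads: List[GenomicInterval] = []
    serial = 0
    for (chrom, strand), lam in sorted(_rate_vectors(cfg, truth, condition).items()):
        if cfg.dispersion > 0:
            # NB with var = m + d m^2, via gamma-Poisson mixture
            r = 1.0 / cfg.dispersion
            counts = rng.poisson(rng.gamma(r, lam / r))
        else:
            counts = rng.poisson(lam)
        nz = np.nonzero(counts)[0]
        bins = np.repeat(nz, counts[nz])
        offs = rng.integers(0, bw, size=bins.size)
        pos = bins * bw + offs
        lens = rng.integers(lmin, lmax + 1, size=bins.size)
        chrom_len = cfg.chrom_lengths[chrom]
        pos = np.minimum(pos, chrom_len - 1)
        for p, l in zip(pos.tolist(), lens.tolist()):
            serial += 1
            if strand == "+":
                iv = GenomicInterval(chrom, p, min(p + l, chrom_len), "+",
                                     f"r{condition[0]}{serial}")
            else:
                iv = GenomicInterval(chrom, max(0, p - l + 1), p + 1, "-",
                                     f"r{condition[0]}{serial}")
            reads.append(iv)
    return reads


# ---------------------------------------------------------------------------
# scoring


def evaluate_calls(
    called: Sequence[TranscriptUnit],
    truth_units: Sequence[TruthUnit],
    jaccard_min: float = 0.8,
) -> Dict[str, float]:
    """Score called units against planted ones by interval Jaccard.

    A truth unit is recovered iff some same-strand called unit reaches the
    Jaccard threshold against it; a called unit is matched iff it reaches
    the threshold against some truth unit.  With no called units precision
    is reported as 1.0 (no false calls) together with ``no_calls = 1``.
    """
    recovered = 0
    boundary_errors: List[float] = []
    called_matched = [False] * len(called)
    for tu in truth_units:
        t_iv = tu.interval
        best = 0.0
        for i, cu in enumerate(called):
            if cu.chrom != tu.chrom or cu.strand != tu.strand:
                continue
            j = cu.interval.jaccard(t_iv)
            if j >= jaccard_min:
                called_matched[i] = True
                if j > best:
                    best = j
                boundary_errors.append(
                    (abs(cu.start - tu.start) + abs(cu.end - tu.end)) / 2
                )
        if best >= jaccard_min:
            recovered += 1
    sensitivity = recovered / len(truth_units) if truth_units else 1.0
    if called:
        precision = sum(called_matched) / len(called)
        no_calls = 0
    else:
        precision, no_calls = 1.0, 1
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "boundary_error_bp": float(np.mean(boundary_errors)) if boundary_errors else 0.0,
        "no_calls": float(no_calls),
    }
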