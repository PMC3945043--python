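"""Rule-based functional classification of called transcript units.

Every unit receives exactly one of eight classes:

==============  ============================================================
protein_coding  >20% of the unit overlaps a well-annotated protein-coding
                gene on the same strand
non_coding      any same-strand overlap with an annotated non-coding RNA
                gene (lncRNA or short ncRNA), with no size/quality
                restriction
divergent       short antisense transcript from an active promoter: >10% of
                the unit overlaps the proximal promoter (TSS +/- 500 bp) of
                a called opposite-strand primary unit >1 kb, and the unit is
                <50% of that primary's size
antisense       >20% of the unit overlaps >20% of a protein-coding or
                lncRNA gene on the opposite strand
repeat          >50% of the unit falls in RepeatMasker regions
intergenic      no overlap with any annotated gene on either strand
eRNA            assigned downstream by the enhancer caller, as a refinement
                of intergenic (paired short bidirectional units)
other_genic     fallback: touches a gene annotation on some strand but
                matches it poorly (<20%)
==============  ============================================================

Rules are evaluated in a fixed precedence order (see
``ClassifierConfig.precedence``); the first match wins, so the classes
partition the input by construction.  All thresholds are strict
inequalities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    overlap_fraction,
    union_overlap_fraction,
)
from .hmm import TranscriptUnit

CLASSES = (
    "protein_coding",
    "non_coding",
    "intergenic",
    "eRNA",
    "divergent",
    "antisense",
    "repeat",
    "other_genic",
)


@dataclass
class ClassifierConfig:
    """Thresholds of the classification rules (strict inequalities).

    Defaults are the published rule constants; the precedence order is a
    documented assumption (divergent before antisense so promoter-proximal
    opposite-strand units keep their own class; repeat after the genic
    rules so genic repeats stay genic).
    """

    protein_overlap_min: float = 0.20
    antisense_self_min: float = 0.20
    antisense_gene_min: float = 0.20
    repeat_overlap_min: float = 0.50
    divergent_promoter_flank: int = 500
    divergent_self_overlap_min: float = 0.10
    divergent_primary_min_len: int = 1000
    divergent_size_ratio_max: float = 0.50
    lncRNA_min_len: int = 200
    other_genic_max_match: float = 0.20
    precedence: Tuple[str, ...] = (
        "protein_coding", "non_coding", "divergent", "antisense", "repeat",
        "intergenic", "other_genic",
    )

    def __post_init__(self) -> None:
        for attr in (
            "protein_overlap_min", "antisense_self_min", "antisense_gene_min",
            "repeat_overlap_min", "divergent_self_overlap_min",
            "divergent_size_ratio_max", "other_genic_max_match",
        ):
            if not (0 < getattr(self, attr) < 1):
                raise ValueError(f"{attr} must lie in (0, 1)")
        for attr in ("divergent_promoter_flank", "divergent_primary_min_len",
                     "lncRNA_min_len"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


@dataclass
class ClassifiedTranscript:
    """A transcript unit plus its functional class and supporting evidence."""

    unit: TranscriptUnit
    cls: str
    rule: str
    evidence_id: Optional[str] = None
    overlap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")


class _AnnotationIndex:
    """Interval trees over annotation records, per chromosome and category group."""

    def __init__(self, ann: AnnotationSet):
        self.trees: Dict[str, IntervalTree] = {}
        self.records: List[Tuple[GenomicInterval, str]] = list(ann)
        for idx, (gene, cat) in enumerate(self.records):
            self.trees.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end, idx
            )

    def overlapping(self, iv: GenomicInterval) -> List[Tuple[GenomicInterval, str]]:
        tree = self.trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [self.records[h.data] for h in tree.overlap(iv.start, iv.end)]
        # deterministic regardless of tree internals / record order
        hits.sort(key=lambda gc: (gc[0].start, gc[0].end, gc[0].name or ""))
        return hits


def _is_repeat(cat: str) -> bool:
    return cat == "repeat"


def _is_noncoding_gene(cat: str) -> bool:
    return cat == "lncRNA" or cat.startswith("short_ncRNA:")


def classify(
    t: TranscriptUnit,
    ann: AnnotationSet | _AnnotationIndex,
    primaries: Sequence[TranscriptUnit],
    cfg: Optional[ClassifierConfig] = None,
) -> ClassifiedTranscript:
    """Classify a single unit against annotations and the called primaries.

    ``primaries`` must contain the called transcript units (the divergent
    rule measures the candidate against the opposite-strand *called* primary
    transcript, not the annotation).
    """
    cfg = cfg or ClassifierConfig()
    index = ann if isinstance(ann, _AnnotationIndex) else _AnnotationIndex(ann)
    iv = t.interval
    hits = index.overlapping(iv)
    gene_hits = [(g, c) for g, c in hits if not _is_repeat(c)]

    for rule in cfg.precedence:
        result = _RULES[rule](t, iv, gene_hits, hits, primaries, cfg)
        if result is not None:
            return result
    # fallback: some gene annotation touched, all matches below threshold
    g, c = gene_hits[0]
    return ClassifiedTranscript(t, "other_genic", "rule_other_genic",
                                g.name, overlap_fraction(iv, g))


def _rule_protein_coding(t, iv, gene_hits, hits, primaries, cfg):
    best = None
    for g, c in gene_hits:
        if c == "protein_coding" and g.strand == iv.strand:
            frac = overlap_fraction(iv, g)
            if frac > cfg.protein_overlap_min and (best is None or frac > best[1]):
                best = (g, frac)
    if best:
        return ClassifiedTranscript(t, "protein_coding", "rule_protein_coding",
                                    best[0].name, best[1])
    return None


def _rule_non_coding(t, iv, gene_hits, hits, primaries, cfg):
    for g, c in gene_hits:
        if _is_noncoding_gene(c) and g.strand == iv.strand:
            return ClassifiedTranscript(t, "non_coding", "rule_non_coding",
                                        g.name, overlap_fraction(iv, g))
    return None


def _rule_divergent(t, iv, gene_hits, hits, primaries, cfg):
    for p in primaries:
        if p.chrom != iv.chrom or p.strand == iv.strand or p.strand == ".":
            continue
        if len(p) <= cfg.divergent_primary_min_len:
            continue
        if len(t) >= cfg.divergent_size_ratio_max * len(p):
            continue
        tss = p.interval.five_prime
        flank = cfg.divergent_promoter_flank
        promoter = GenomicInterval(p.chrom, max(0, tss - flank), tss + flank + 1)
        frac = overlap_fraction(iv, promoter)
        if frac > cfg.divergent_self_overlap_min:
            return ClassifiedTranscript(t, "divergent", "rule_divergent", p.id, frac)
    return None


def _rule_antisense(t, iv, gene_hits, hits, primaries, cfg):
    for g, c in gene_hits:
        if c not in ("protein_coding", "lncRNA"):
            continue
        if g.strand == iv.strand or g.strand == "." or iv.strand == ".":
            continue
        self_frac = overlap_fraction(iv, g)
        gene_frac = overlap_fraction(g, iv)
        if self_frac > cfg.antisense_self_min and gene_frac > cfg.antisense_gene_min:
            return ClassifiedTranscript(t, "antisense", "rule_antisense",
                                        g.name, self_frac)
    return None


def _rule_repeat(t, iv, gene_hits, hits, primaries, cfg):
    repeats = [g for g, c in hits if _is_repeat(c)]
    if not repeats:
        return None
    frac = union_overlap_fraction(iv, repeats)
    if frac > cfg.repeat_overlap_min:
        return ClassifiedTranscript(t, "repeat", "rule_repeat",
                                    repeats[0].name, frac)
    return None


def _rule_intergenic(t, iv, gene_hits, hits, primaries, cfg):
    if not gene_hits:
        return ClassifiedTranscript(t, "intergenic", "rule_intergenic", None, 0.0)
    return None


def _rule_other_genic(t, iv, gene_hits, hits, primaries, cfg):
    return None  # handled as the final fallback in classify()


_RULES = {
    "protein_coding": _rule_protein_coding,
    "non_coding": _rule_non_coding,
    "divergent": _rule_divergent,
    "antisense": _rule_antisense,
    "repeat": _rule_repeat,
    "intergenic": _rule_intergenic,
    "other_genic": _rule_other_genic,
}


def classify_all(
    units: Sequence[TranscriptUnit],
    ann: AnnotationSet,
    cfg: Optional[ClassifierConfig] = None,
) -> Tuple[List[ClassifiedTranscript], Counter]:
    """Classify every unit exactly once; returns (records, class counts).

    The counts always sum to ``len(units)`` — the classes partition the
    input by construction.
    """
    cfg = cfg or ClassifierConfig()
    index = _AnnotationIndex(ann)
    out = [classify(u, index, units, cfg) for u in units]
    counts = Counter(ct.cls for ct in out)
    assert sum(counts.values()) == len(units)
    return out, counts
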