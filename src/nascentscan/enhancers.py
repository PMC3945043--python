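"""Bidirectional eRNA pairing, NF-kB overlap, and target-gene assignment.

Active enhancers produce short bidirectional transcripts.  A candidate
enhancer is a pair of opposite-strand intergenic units, each shorter than
9 kb, whose intervals overlap; the midpoint of the overlap anchors all
downstream analyses.  Pairs whose center lies within 1 kb of an NF-kB p65
ChIP-seq peak center are flagged NF-kB enhancers.  The putative target is
the protein-coding or lncRNA gene with the nearest TSS in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .intervals import AnnotationSet, GenomicInterval
from .classify import ClassifiedTranscript
from .hmm import TranscriptUnit


@dataclass
class EnhancerPair:
    """Two overlapping, opposite-strand short intergenic transcripts."""

    plus_unit: TranscriptUnit
    minus_unit: TranscriptUnit
    center: int = field(init=False)
    nfkb: Optional[bool] = None
    target_gene: Optional[str] = None
    target_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.plus_unit.strand != "+" or self.minus_unit.strand != "-":
            raise ValueError("pair must be one + and one - unit")
        if self.plus_unit.chrom != self.minus_unit.chrom:
            raise ValueError("pair units on different chromosomes")
        if self.intersection() <= 0:
            raise ValueError("pair units do not overlap")
        self.center = pair_center(self)

    @property
    def chrom(self) -> str:
        return self.plus_unit.chrom

    def intersection(self) -> int:
        return self.plus_unit.interval.intersection_length(self.minus_unit.interval)

    def intersection_interval(self) -> Tuple[int, int]:
        s = max(self.plus_unit.start, self.minus_unit.start)
        e = min(self.plus_unit.end, self.minus_unit.end)
        return s, e


def pair_center(pair: EnhancerPair) -> int:
    """Midpoint of the overlap of the two units (floor of the mean)."""
    s, e = pair.intersection_interval()
    return (s + e) // 2


def pair_ernas(
    intergenic: Sequence[ClassifiedTranscript],
    max_len: int = 9000,
) -> List[EnhancerPair]:
    """Pair overlapping opposite-strand short intergenic units into eRNAs.

    Every (+, -) pair with nonzero interval intersection and both unit
    lengths < ``max_len`` is a candidate.  Each unit joins at most one pair:
    candidates are ranked by intersection length (largest first, ties to the
    leftmost partner) and matched greedily.  Paired units are re-labelled
    class ``eRNA`` in place.
    """
    for ct in intergenic:
        if ct.cls != "intergenic":
            raise ValueError(
                f"unit {ct.unit.id} has class {ct.cls!r}; pairing expects intergenic"
            )
    plus = [ct for ct in intergenic if ct.unit.strand == "+" and len(ct.unit) < max_len]
    minus = [ct for ct in intergenic if ct.unit.strand == "-" and len(ct.unit) < max_len]
    candidates = []
    for p in plus:
        for m in minus:
            inter = p.unit.interval.intersection_length(m.unit.interval)
            if inter > 0:
                candidates.append((inter, p, m))
    candidates.sort(
        key=lambda c: (
            -c[0],
            min(c[1].unit.start, c[2].unit.start),
            c[1].unit.start, c[2].unit.start,
        )
    )
    used = set()
    pairs: List[EnhancerPair] = []
    for _inter, p, m in candidates:
        if id(p) in used or id(m) in used:
            continue
        used.update((id(p), id(m)))
        pairs.append(EnhancerPair(p.unit, m.unit))
        for ct in (p, m):
            ct.cls = "eRNA"
            ct.rule = "rule_erna_pair"
    pairs.sort(key=lambda pr: (pr.chrom, pr.center))
    return pairs


def flag_nfkb(
    pair: EnhancerPair,
    peaks: Sequence[GenomicInterval],
    radius: int = 1000,
) -> bool:
    """True iff an NF-kB peak center lies within ``radius`` bp of the pair
    center (inclusive boundary)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    for peak in peaks:
        if peak.chrom != pair.chrom:
            continue
        peak_center = (peak.start + peak.end) // 2
        if abs(peak_center - pair.center) <= radius:
            return True
    return False


def nearest_gene(
    pair: EnhancerPair,
    ann: AnnotationSet,
) -> Tuple[Optional[str], Optional[int]]:
    """Nearest protein-coding or lncRNA TSS in either direction.

    Returns ``(gene_id, signed_distance)``; distance is negative when the
    TSS lies left of the pair center.  Exact distance ties break by
    lexicographic gene id.  ``(None, None)`` when the chromosome has no
    eligible gene.
    """
    best: Optional[Tuple[int, str, int]] = None
    for gene, _cat in ann.by_category("protein_coding", "lncRNA"):
        if gene.chrom != pair.chrom:
            continue
        signed = gene.five_prime - pair.center
        key = (abs(signed), gene.name or "")
        if best is None or key < (best[0], best[1]):
            best = (abs(signed), gene.name or "", signed)
    if best is None:
        return None, None
    return best[1] or None, best[2]


def annotate_pairs(
    pairs: Sequence[EnhancerPair],
    peaks: Sequence[GenomicInterval],
    ann: AnnotationSet,
    radius: int = 1000,
) -> List[EnhancerPair]:
    """Fill in the NF-kB flag and nearest-target fields of every pair."""
    for pair in pairs:
        pair.nfkb = flag_nfkb(pair, peaks, radius)
        pair.target_gene, pair.target_distance = nearest_gene(pair, ann)
    return list(pairs)
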