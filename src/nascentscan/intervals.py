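"""Core genomic coordinate types.

All coordinates are 0-based, half-open (BED-native) everywhere inside the
package; formats with other conventions (GTF, wiggle) are converted exactly
once, on read or write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

VALID_STRANDS = ("+", "-", ".")

#: Annotation category labels.  Short non-coding RNAs carry their subtype as
#: a suffix, e.g. ``short_ncRNA:tRNA``.
PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
SHORT_NCRNA_PREFIX = "short_ncRNA:"
REPEAT = "repeat"


@dataclass
class GenomicInterval:
    """A stranded genomic interval: ``chrom:[start, end)`` on ``strand``.

    ``start`` is 0-based inclusive, ``end`` exclusive.  ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' end (TSS for genes): ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand != "-" else self.end - 1

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomicInterval") -> float:
        """Interval Jaccard: |intersection| / |union| (0 across chromosomes)."""
        inter = self.intersection_length(other)
        if inter == 0:
            return 0.0
        union = len(self) + len(other) - inter
        return inter / union


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b``; strand is ignored at this level."""
    if len(a) == 0:  # unreachable for validated intervals, kept for raw use
        raise ValueError("zero-length interval has no overlap fraction")
    return a.intersection_length(b) / len(a)


def union_overlap_fraction(a: GenomicInterval, others: Iterable[GenomicInterval]) -> float:
    """Fraction of ``a`` covered by the union of ``others`` (same chromosome)."""
    segs = sorted(
        (max(a.start, o.start), min(a.end, o.end))
        for o in others
        if o.chrom == a.chrom and o.start < a.end and o.end > a.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / len(a)


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp.

    The rDNA repeat unit, when used as a single mapping reference, is simply
    one more entry here — no special handling anywhere downstream.
    """

    def __init__(self, mapping: Optional[dict] = None):
        super().__init__()
        if mapping:
            for name, length in mapping.items():
                self[name] = length

    def __setitem__(self, name: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(name, length)

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                f"chromosome end ({self[iv.chrom]})"
            )


@dataclass
class AnnotationSet:
    """Gene annotations as primary-transcript spans with category labels.

    Exon structure is deliberately discarded: every classification rule
    compares against the whole primary-transcript span.  Categories are
    ``protein_coding``, ``lncRNA``, ``short_ncRNA:<subtype>`` and ``repeat``.
    """

    genes: list = field(default_factory=list)  # list[(GenomicInterval, category)]

    def add(self, gene: GenomicInterval, category: str) -> None:
        self.genes.append((gene, category))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator:
        return iter(self.genes)

    def by_category(self, *categories: str) -> list:
        """Genes whose category equals, or whose prefixed category starts
        with, any of the given labels (``short_ncRNA`` matches all subtypes)."""
        out = []
        for gene, cat in self.genes:
            for want in categories:
                if cat == want or cat.startswith(want + ":"):
                    out.append((gene, cat))
                    break
        return out

    def tss(self, gene: GenomicInterval) -> int:
        return gene.five_prime
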