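"""Readers and writers for the genomic text formats the pipeline touches.

BED3/BED6, BED12 and GTF in; BED6, fixedStep wiggle and bedGraph out, plus
two-column chromosome-size tables.  Internal coordinates are 0-based
half-open; GTF (1-based inclusive) and wiggle (1-based) are converted at the
boundary, exactly once.
"""

from __future__ import annotations

import logging
import math
import re
from typing import Dict, Iterable, List, Optional, TextIO, Tuple, Union

import numpy as np

from .intervals import AnnotationSet, ChromSizes, GenomicInterval
from .tracks import WindowedTrack

log = logging.getLogger(__name__)

PathLike = Union[str, "os.PathLike[str]"]


class BedParseError(ValueError):
    """Malformed record in a BED-family file; message names the line."""


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from None
    if not (0 <= start < end):
        raise BedParseError(f"line {lineno}: require 0 <= start < end, got {start}, {end}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: Optional[float] = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-numeric score {fields[4]!r}") from None
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in ("+", "-", "."):
        raise BedParseError(f"line {lineno}: invalid strand {strand!r}")
    return GenomicInterval(chrom, start, end, strand, name, score)


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, preserving file order.

    Records without a strand column come back unstranded (``.``).  Track
    definition lines, comments and blank lines are skipped.
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed_line(line, lineno))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write intervals as BED6 (name '.', score 0 where absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_chrom_sizes(path: PathLike) -> ChromSizes:
    """Read a two-column <name> <length> TSV (UCSC chrom.sizes convention)."""
    sizes = ChromSizes()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected name and length")
            if fields[0] in sizes:
                raise ValueError(f"{path}: line {lineno}: duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# wiggle / bedGraph

def _rebin(values: np.ndarray, bin_width: int, step: int) -> np.ndarray:
    if step == bin_width:
        return values
    if step <= 0 or step % bin_width != 0:
        raise ValueError(
            f"step {step} is not a positive multiple of bin width {bin_width}"
        )
    factor = step // bin_width
    n_out = math.ceil(len(values) / factor)
    padded = np.zeros(n_out * factor)
    padded[: len(values)] = values
    return padded.reshape(n_out, factor).sum(axis=1)


def write_wiggle(track: WindowedTrack, path_or_fh: Union[PathLike, TextIO],
                 step: int = 200, append: bool = False) -> None:
    """Write a track as fixedStep wiggle in non-overlapping ``step``-bp windows.

    Finer bins are re-binned by summation; ``step`` must be a multiple of the
    track's bin width.  Wiggle positions are 1-based (start=1 is the first
    base of the chromosome).
    """
    values = _rebin(track.values, track.bin_width, step)
    close = False
    if not hasattr(path_or_fh, "write"):
        path_or_fh = open(path_or_fh, "a" if append else "w")
        close = True
    try:
        path_or_fh.write(
            f"fixedStep chrom={track.chrom} start=1 step={step} span={step}\n"
        )
        for v in values:
            path_or_fh.write(f"{int(v) if float(v).is_integer() else v}\n")
    finally:
        if close:
            path_or_fh.close()


def read_wiggle(path: PathLike) -> Dict[str, Tuple[int, np.ndarray]]:
    """Read fixedStep wiggle back as {chrom: (step, values)} (round-trip aid)."""
    out: Dict[str, Tuple[int, np.ndarray]] = {}
    chrom, step, vals = None, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("fixedStep"):
                if chrom is not None:
                    out[chrom] = (step, np.array(vals))
                attrs = dict(kv.split("=") for kv in line.split()[1:])
                chrom, step, vals = attrs["chrom"], int(attrs["step"]), []
                if int(attrs.get("start", 1)) != 1:
                    raise ValueError("only start=1 fixedStep blocks are supported")
            elif line:
                vals.append(float(line))
    if chrom is not None:
        out[chrom] = (step, np.array(vals))
    return out


def write_bedgraph(track: WindowedTrack, path_or_fh: Union[PathLike, TextIO],
                   append: bool = False) -> None:
    """bedGraph alternative output (0-based half-open, zero bins skipped)."""
    close = False
    if not hasattr(path_or_fh, "write"):
        path_or_fh = open(path_or_fh, "a" if append else "w")
        close = True
    try:
        bw = track.bin_width
        for i, v in enumerate(track.values):
            if v != 0:
                path_or_fh.write(f"{track.chrom}\t{i * bw}\t{(i + 1) * bw}\t{v:g}\n")
    finally:
        if close:
            path_or_fh.close()


# ---------------------------------------------------------------------------
# annotations

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')

#: GTF attribute keys searched, in order, for a biotype.
_BIOTYPE_KEYS = ("gene_biotype", "transcript_type", "transcript_biotype", "gene_type")

#: Default mapping from common biotype tokens to annotation categories.
DEFAULT_CATEGORY_MAP = {
    "protein_coding": "protein_coding",
    "lincRNA": "lncRNA",
    "lncRNA": "lncRNA",
    "antisense": "lncRNA",
    "miRNA": "short_ncRNA:miRNA",
    "tRNA": "short_ncRNA:tRNA",
    "snRNA": "short_ncRNA:snRNA",
    "snoRNA": "short_ncRNA:snoRNA",
    "scRNA": "short_ncRNA:scRNA",
    "rRNA": "short_ncRNA:rRNA",
    "repeat": "repeat",
}


def read_annotations(
    path: PathLike,
    format: str = "gtf",
    category_map: Optional[Dict[str, str]] = None,
) -> AnnotationSet:
    """Read gene annotations as whole primary-transcript spans.

    Exon structure (GTF exon features, BED12 blocks) is ignored: every
    downstream comparison is against the unspliced transcript span.  For GTF,
    ``transcript`` (or, failing that, ``gene``) features are used and the
    biotype is looked up in ``category_map``; unmapped biotypes are dropped
    with a logged warning.  For BED12 the name column is looked up instead.
    """
    category_map = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    ann = AnnotationSet()
    if format == "gtf":
        _read_gtf(path, category_map, ann)
    elif format == "bed12":
        _read_bed12(path, category_map, ann)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return ann


def _read_gtf(path: PathLike, category_map: Dict[str, str], ann: AnnotationSet) -> None:
    rows: List[Tuple[str, GenomicInterval]] = []
    features_seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_str = fields[:9]
            features_seen.add(feature)
            if feature not in ("transcript", "gene"):
                continue
            attrs = dict(_GTF_ATTR.findall(attr_str))
            biotype = next(
                (attrs[k] for k in _BIOTYPE_KEYS if k in attrs), None
            )
            if biotype is None or biotype not in category_map:
                log.warning(
                    "%s line %d: biotype %r not in category map; record skipped",
                    path, lineno, biotype,
                )
                continue
            name = attrs.get("transcript_id") or attrs.get("gene_id")
            # GTF is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand, name)
            rows.append((feature, iv, category_map[biotype]))
    use = "transcript" if any(f == "transcript" for f, _, _ in rows) else "gene"
    for feature, iv, cat in rows:
        if feature == use:
            ann.add(iv, cat)


def _read_bed12(path: PathLike, category_map: Dict[str, str], ann: AnnotationSet) -> None:
    for iv in read_bed(path):
        if iv.name is None or iv.name not in category_map:
            log.warning("BED12 record %s: name not in category map; skipped", iv.name)
            continue
        ann.add(iv, category_map[iv.name])
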