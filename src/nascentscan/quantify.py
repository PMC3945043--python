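"""Per-transcript read counting, regulation tables, GSEA pre-ranking and
metagene profiles.

Differential testing itself is delegated to external count-based tools
(e.g. edgeR): this module emits the count matrix they consume and
re-ingests their result table (id, log fold change, p, q).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .hmm import TranscriptUnit


def count_in_intervals(
    reads: Iterable[GenomicInterval],
    units: Sequence[TranscriptUnit],
    sample: str = "sample",
) -> pd.Series:
    """Count reads per transcript unit (one count-matrix column).

    A read is counted for the same-strand unit containing its 5' end; reads
    falling in no unit are uncounted.  Units must be non-overlapping per
    strand.
    """
    per_strand: Dict[Tuple[str, str], List[TranscriptUnit]] = {}
    for u in units:
        per_strand.setdefault((u.chrom, u.strand), []).append(u)
    lookup = {}
    for key, us in per_strand.items():
        us.sort(key=lambda u: u.start)
        for a, b in zip(us, us[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"units {a.id} and {b.id} overlap on {key[0]} strand {key[1]}"
                )
        lookup[key] = (
            np.array([u.start for u in us]),
            np.array([u.end for u in us]),
            us,
        )
    acc = {u.id: 0 for u in units}
    for read in reads:
        entry = lookup.get((read.chrom, read.strand))
        if entry is None:
            continue
        starts, ends, us = entry
        pos = read.five_prime
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            acc[us[i].id] += 1
    return pd.Series(acc, name=sample, dtype=int)


def build_count_matrix(columns: Sequence[pd.Series]) -> pd.DataFrame:
    """Assemble per-sample count columns into a count matrix with library
    sizes stored in ``df.attrs['library_sizes']``."""
    df = pd.concat(columns, axis=1).fillna(0).astype(int)
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample names")
    df.attrs["library_sizes"] = df.sum(axis=0).to_dict()
    return df


# ---------------------------------------------------------------------------
# regulation tables and GSEA ranking

REG_COLUMNS = ("id", "lfc", "p", "q")


def apply_regulation_threshold(table: pd.DataFrame, q_max: float = 0.001) -> pd.DataFrame:
    """Flag regulated transcripts at a strict FDR-corrected q cutoff.

    Adds ``regulated`` (q < q_max, strict) and ``direction``
    (up/down/<NA> from the sign of the log fold change).
    """
    if "q" not in table.columns:
        raise ValueError("regulation table lacks a 'q' column")
    q = table["q"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q values must lie in [0, 1]")
    out = table.copy()
    out["regulated"] = q < q_max
    direction = pd.Series(pd.NA, index=table.index, dtype="object")
    direction[out["regulated"] & (out["lfc"] > 0)] = "up"
    direction[out["regulated"] & (out["lfc"] < 0)] = "down"
    out["direction"] = direction
    return out


def build_gsea_ranking(table: pd.DataFrame, fdr_cut: float = 0.001) -> List[str]:
    """Order genes for pre-ranked GSEA in three blocks.

    Significantly regulated genes (q < ``fdr_cut``) go to the extremes:
    upregulated at the top ordered by descending fold change, downregulated
    at the bottom ordered by ascending fold change.  Non-significant genes
    fill the middle: the upregulated side ordered by ascending p, then the
    downregulated side ordered by descending p.  Ties break by gene id, so
    the ordering is deterministic; the output is a permutation of the input
    ids.
    """
    for col in ("id", "lfc", "p", "q"):
        if col not in table.columns:
            raise ValueError(f"regulation table lacks a {col!r} column")
    df = table.copy()
    sig = df["q"] < fdr_cut
    up = df[sig & (df["lfc"] > 0)].sort_values(
        ["lfc", "id"], ascending=[False, True])
    down = df[sig & (df["lfc"] <= 0)].sort_values(
        ["lfc", "id"], ascending=[True, True])
    mid = df[~sig]
    mid_up = mid[mid["lfc"] > 0].sort_values(["p", "id"], ascending=[True, True])
    mid_down = mid[mid["lfc"] <= 0].sort_values(["p", "id"], ascending=[False, True])
    return list(pd.concat([up, mid_up, mid_down, down])["id"])


def write_rnk(ranking: Sequence[str], path) -> None:
    """Write a two-column .rnk file (id, descending integer rank score)."""
    with open(path, "w") as fh:
        n = len(ranking)
        for i, gene in enumerate(ranking):
            fh.write(f"{gene}\t{n - i}\n")


# ---------------------------------------------------------------------------
# metagene profiles


@dataclass
class MetageneProfile:
    """Average read density around aligned anchors.

    ``offsets`` are the left edges of the offset bins, from ``-flank`` to
    ``+flank``; ``mean_density`` is reads per bin per anchor.  For stranded
    signal the sense and antisense profiles are reported separately.
    """

    offsets: np.ndarray
    mean_density: np.ndarray
    n_anchors: int
    signal_strand: str = "combined"  # sense | antisense | combined


def metagene(
    reads: Iterable[GenomicInterval],
    anchors: Sequence[Tuple[str, int, str]],
    flank: int = 4000,
    bin: int = 25,
    stranded: bool = True,
) -> Dict[str, MetageneProfile]:
    """Average read 5'-end density around anchors ``(chrom, position, strand)``.

    Offsets are strand-aware: upstream of the anchor is negative on both
    strands (minus-strand anchors mirror genomic offsets).  With
    ``stranded`` the profile is split into sense (read strand == anchor
    strand) and antisense; otherwise a single combined profile is returned
    (ChIP-style signal).  Offset bins are half-open ``[k*bin, (k+1)*bin)``
    with k from ``-flank/bin`` to ``+flank/bin``.
    """
    if not anchors:
        raise ValueError("no anchors")
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of the bin size")
    n_half = flank // bin
    n_bins = 2 * n_half + 1
    offsets = (np.arange(n_bins) - n_half) * bin
    keys = ("sense", "antisense") if stranded else ("combined",)
    sums = {k: np.zeros(n_bins) for k in keys}
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for chrom, pos, strand in anchors:
        by_chrom.setdefault(chrom, []).append((pos, strand))
    positions = {c: sorted(a) for c, a in by_chrom.items()}
    reach = flank + bin  # anchors farther than this cannot receive the read
    for read in reads:
        anchor_list = positions.get(read.chrom)
        if anchor_list is None:
            continue
        e5 = read.five_prime
        lo = bisect.bisect_left(anchor_list, (e5 - reach,))
        hi = bisect.bisect_right(anchor_list, (e5 + reach, "~"))
        for pos, astrand in anchor_list[lo:hi]:
            s = e5 - pos if astrand != "-" else pos - e5
            idx = s // bin + n_half  # floor division: half-open offset bins
            if 0 <= idx < n_bins:
                if not stranded:
                    sums["combined"][idx] += 1
                elif read.strand == astrand:
                    sums["sense"][idx] += 1
                else:
                    sums["antisense"][idx] += 1
    n = len(anchors)
    return {
        k: MetageneProfile(offsets.copy(), v / n, n, k) for k, v in sums.items()
    }


def profile_to_frame(profiles: Dict[str, MetageneProfile]) -> pd.DataFrame:
    """Tabulate profiles as offset x strand-of-signal mean densities."""
    first = next(iter(profiles.values()))
    data = {"offset": first.offsets}
    for k, p in profiles.items():
        data[k] = p.mean_density
    return pd.DataFrame(data)
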