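"""Binned read-density tracks and the alpha-amanitin control subtraction.

GRO-seq reads mark the position of an engaged polymerase, so a read
contributes a single count at the bin containing its strand-aware 5' end
rather than fractional coverage.  The alpha-amanitin correction isolates
transcription that survives Pol II inhibition: the vehicle-control signal is
subtracted after a running maximum (window of three bins) and re-centred by
the control's mean positive signal, then clamped at zero so the corrected
track remains a valid HMM observation sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d

from .intervals import ChromSizes, GenomicInterval


@dataclass
class WindowedTrack:
    """Per-chromosome, per-strand vector of binned read signal.

    ``values[i]`` covers bases ``[i * bin_width, (i+1) * bin_width)``.
    ``total_reads`` is set once the track has been depth-normalized and is
    ``None`` for raw counts.
    """

    chrom: str
    strand: str
    bin_width: int
    values: np.ndarray
    total_reads: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def same_shape(self, other: "WindowedTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.bin_width == other.bin_width
            and self.n_bins == other.n_bins
        )

    def bin_range(self, start: int, end: int) -> np.ndarray:
        """Values of the bins overlapping base interval [start, end)."""
        lo = start // self.bin_width
        hi = -(-end // self.bin_width)
        return self.values[lo:hi]


def bin_reads(
    reads: Iterable[GenomicInterval],
    sizes: ChromSizes,
    bin_width: int,
    strand: str,
) -> Dict[str, WindowedTrack]:
    """Count read 5' ends per ``bin_width`` bin, for one strand.

    Returns one track per chromosome in ``sizes`` (all-zero where no reads
    map).  Reads on the other strand are ignored; a read extending past its
    chromosome end is an error naming the read.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    tracks = {
        chrom: WindowedTrack(
            chrom, strand, bin_width, np.zeros(math.ceil(length / bin_width))
        )
        for chrom, length in sizes.items()
    }
    for read in reads:
        if read.strand != strand:
            continue
        if read.chrom not in sizes:
            raise ValueError(f"read {read} on unknown chromosome {read.chrom!r}")
        if read.end > sizes[read.chrom]:
            raise ValueError(f"read {read} extends past end of {read.chrom}")
        tracks[read.chrom].values[read.five_prime // bin_width] += 1
    return tracks


def normalize_depth(track: WindowedTrack, total_reads: int) -> WindowedTrack:
    """Scale to reads-per-million: values * 1e6 / total_reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return replace(
        track, values=track.values * (1e6 / total_reads), total_reads=total_reads
    )


def running_max(values: Sequence[float], k: int = 3) -> np.ndarray:
    """Centered running maximum over ``k`` bins, truncated at the ends.

    ``k`` must be odd; ``k = 1`` is the identity.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("window size k must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return values.copy()
    # edge replication equals window truncation for a max filter
    return maximum_filter1d(values, size=k, mode="nearest")


def mean_positive(values: Sequence[float]) -> float:
    """Mean of the strictly positive entries; 0.0 when there are none."""
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    return float(pos.mean()) if pos.size else 0.0


def amanitin_subtract(
    treated: WindowedTrack, control: WindowedTrack, k: int = 3
) -> WindowedTrack:
    """Subtract the Pol II (vehicle-control) signal from the alpha-amanitin track.

    corrected[i] = max(0, treated[i] - running_max(control, k)[i]
                          + mean_positive(control))

    The running maximum makes the subtraction robust to single-bin jitter in
    polymerase position between conditions; the mean-positive baseline keeps
    bins with genuine amanitin-resistant signal above zero.  Both tracks must
    be depth-normalized and share chrom/strand/bin geometry.
    """
    if not treated.same_shape(control):
        raise ValueError("treated and control tracks have mismatched geometry")
    corrected = treated.values - running_max(control.values, k) + mean_positive(
        control.values
    )
    np.clip(corrected, 0.0, None, out=corrected)
    return replace(treated, values=corrected)


def assign_polymerase(
    transcript: GenomicInterval,
    treated: WindowedTrack,
    control: WindowedTrack,
    ratio_threshold: float = 1.0,
) -> str:
    """Label a transcript ``pol2`` or ``non_pol2`` from amanitin response.

    Compares the mean depth-normalized density over the transcript between
    the alpha-amanitin (``treated``) and vehicle (``control``) conditions.
    Transcription relatively enriched under amanitin (ratio >= threshold) is
    non-Pol II (Pol I/III); depleted transcription is Pol II.
    """
    if len(transcript) == 0:
        raise ValueError("zero-length transcript")
    t_mean = float(np.mean(treated.bin_range(transcript.start, transcript.end)))
    c_mean = float(np.mean(control.bin_range(transcript.start, transcript.end)))
    if c_mean == 0:
        return "non_pol2" if t_mean > 0 else "pol2"
    return "non_pol2" if t_mean / c_mean >= ratio_threshold else "pol2"
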