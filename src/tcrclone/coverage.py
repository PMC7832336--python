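"""Binned coverage tracks over a locus.

A :class:`CoverageTrack` holds mean per-base depth per fixed-width bin for a
single sample over one genomic interval.  Tumor and matched normal are kept
as a pair of tracks throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .loci import DepthRecord, GenomicInterval


@dataclass
class CoverageTrack:
    """Mean per-base depth per bin for one sample over ``interval``.

    Bins are half-open ``[start + i*bin_size, start + (i+1)*bin_size)``; the
    last bin may be truncated by the interval end.
    """

    interval: GenomicInterval
    bin_size: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        expected = n_bins(self.interval, self.bin_size)
        if len(self.values) != expected:
            raise ValueError(
                f"{len(self.values)} bins supplied, interval needs {expected}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("bin depths must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_starts(self) -> np.ndarray:
        """0-based genomic start coordinate of every bin."""
        return self.interval.start + self.bin_size * np.arange(self.n_bins)

    def mean_depth(self) -> float:
        return float(np.mean(self.values))

    def median_depth(self) -> float:
        return float(np.median(self.values))

    def same_bins(self, other: "CoverageTrack") -> bool:
        return (
            self.interval == other.interval
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
        )

    def slice_bp(self, start_bp: int, end_bp: int) -> "CoverageTrack":
        """Sub-track over [start_bp, end_bp), snapped outward to bin edges."""
        if not (self.interval.start <= start_bp < end_bp <= self.interval.end):
            raise ValueError("slice outside track interval")
        first = (start_bp - self.interval.start) // self.bin_size
        last = -(-(end_bp - self.interval.start) // self.bin_size)  # ceil
        sub_iv = GenomicInterval(
            self.interval.chrom,
            self.interval.start + first * self.bin_size,
            min(self.interval.start + last * self.bin_size, self.interval.end),
        )
        return CoverageTrack(sub_iv, self.bin_size, self.values[first:last])

    def rebin(self, factor: int) -> "CoverageTrack":
        """Aggregate ``factor`` consecutive bins into one (mean of means).

        Trailing bins that do not fill a whole coarse bin are dropped, and the
        track interval is shortened accordingly.
        """
        if factor < 1:
            raise ValueError("rebin factor must be >= 1")
        if factor == 1:
            return self
        n_coarse = self.n_bins // factor
        if n_coarse == 0:
            raise ValueError("track too short to rebin by that factor")
        vals = self.values[: n_coarse * factor].reshape(n_coarse, factor).mean(axis=1)
        new_iv = GenomicInterval(
            self.interval.chrom,
            self.interval.start,
            self.interval.start + n_coarse * factor * self.bin_size,
        )
        return CoverageTrack(new_iv, self.bin_size * factor, vals)


def n_bins(interval: GenomicInterval, bin_size: int) -> int:
    return -(-len(interval) // bin_size)


def bin_depth_records(
    records: Sequence[DepthRecord] | Iterable[DepthRecord],
    interval: GenomicInterval,
    bin_size: int,
) -> CoverageTrack:
    """Bin per-base depth records into a track (missing positions count 0).

    Every base of ``interval`` contributes to its bin's mean, so sparse
    input behaves as if densified with zeros first.
    """
    nb = n_bins(interval, bin_size)
    sums = np.zeros(nb)
    for r in records:
        if r.chrom != interval.chrom:
            continue
        if interval.start <= r.pos < interval.end:
            sums[(r.pos - interval.start) // bin_size] += r.depth
    widths = np.full(nb, bin_size, dtype=float)
    rem = len(interval) % bin_size
    if rem:
        widths[-1] = rem
    return CoverageTrack(interval, bin_size, sums / widths)


def track_from_depth_tsv(
    path, interval: GenomicInterval, bin_size: int
) -> CoverageTrack:
    """Read a samtools-depth TSV and bin it over ``interval``."""
    from .loci import read_depth_tsv

    return bin_depth_records(read_depth_tsv(path, interval), interval, bin_size)
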