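"""Binning and log transformation of peak-level single-cell count matrices.

Peaks are collapsed onto fixed-width genomic bins (read counts of peaks in
the same bin are summed) and the binned matrix is natural-log transformed
as ``log(count + 1)``. Each chromosome is processed independently; only
bins containing at least one peak become model variables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 25_000


@dataclass(frozen=True, order=True)
class GenomicBin:
    """A fixed-width genomic bin, 0-based half-open."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid bin interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakCountMatrix:
    """Raw cells x peaks count matrix with peak coordinates.

    ``peaks`` holds ``(chrom, start, end, id)`` tuples, one per count column.
    """

    counts: np.ndarray
    peaks: list[tuple[str, int, int, str]]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x peaks matrix")
        if self.counts.shape[1] != len(self.peaks):
            raise ValueError(
                f"{self.counts.shape[1]} count columns but {len(self.peaks)} peak records"
            )
        if self.counts.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"{self.counts.shape[0]} count rows but {len(self.cell_ids)} cell ids"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        for chrom, start, end, _ in self.peaks:
            if start >= end:
                raise ValueError(f"invalid peak interval {chrom}:{start}-{end}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[1]


@dataclass
class BinnedCellMatrix:
    """Log-transformed cells x occupied-bins matrix for one chromosome."""

    values: np.ndarray
    bins: list[GenomicBin]
    cell_ids: list[str]
    chrom: str
    log_base: str = "e"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.bins):
            raise ValueError("values columns must match bins")
        if any(b.chrom != self.chrom for b in self.bins):
            raise ValueError("all bins must belong to the matrix chromosome")
        starts = [b.start for b in self.bins]
        if starts != sorted(starts):
            raise ValueError("bins must be sorted by start")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def bin_genome(
    chrom_sizes: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE
) -> dict[str, list[GenomicBin]]:
    """Divide each chromosome into ``bin_size`` bins; last bin truncated.

    Returns a mapping chromosome -> sorted list of :class:`GenomicBin`.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    out: dict[str, list[GenomicBin]] = {}
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        n = math.ceil(length / bin_size)
        out[chrom] = [
            GenomicBin(chrom, i * bin_size, min((i + 1) * bin_size, length), i)
            for i in range(n)
        ]
    return out


def merge_peaks_into_bins(
    pm: PeakCountMatrix, bins: Sequence[GenomicBin]
) -> tuple[np.ndarray, list[GenomicBin]]:
    """Sum peak counts into the bins of one chromosome.

    A peak is assigned to the single bin containing its midpoint, which
    conserves total read counts for boundary-spanning peaks. Peaks on other
    chromosomes are ignored here; bins without any peak are dropped.

    Returns ``(counts, occupied_bins)`` where ``counts`` is cells x occupied
    bins in genomic order.
    """
    if not bins:
        raise ValueError("empty bin list")
    chrom = bins[0].chrom
    if any(b.chrom != chrom for b in bins):
        raise ValueError("bins must all be on one chromosome")
    bin_size = bins[0].end - bins[0].start if len(bins) == 1 else bins[1].start - bins[0].start
    chrom_end = bins[-1].end

    per_bin: dict[int, np.ndarray] = {}
    n_skipped = 0
    for col, (p_chrom, start, end, _pid) in enumerate(pm.peaks):
        if p_chrom != chrom:
            continue
        mid = (start + end) // 2
        if mid >= chrom_end or mid < 0:
            n_skipped += 1
            continue
        idx = mid // bin_size
        counts_col = np.asarray(pm.counts[:, col])
        if idx in per_bin:
            per_bin[idx] = per_bin[idx] + counts_col
        else:
            per_bin[idx] = counts_col.copy()
    if n_skipped:
        logger.warning("skipped %d peaks with midpoints outside %s bins", n_skipped, chrom)

    occupied = sorted(per_bin)
    bin_by_index = {b.index: b for b in bins}
    occupied_bins = [bin_by_index[i] for i in occupied]
    if occupied:
        merged = np.column_stack([per_bin[i] for i in occupied])
    else:
        merged = np.zeros((pm.n_cells, 0), dtype=pm.counts.dtype)
    return merged, occupied_bins


def log_transform(counts: np.ndarray) -> np.ndarray:
    """Elementwise natural log of ``counts + 1``."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("log_transform requires non-negative input")
    return np.log1p(counts)


def bin_matrix(
    pm: PeakCountMatrix,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, BinnedCellMatrix]:
    """Full preprocessing: bin, merge and log-transform, per chromosome.

    Peaks on chromosomes absent from ``chrom_sizes`` are skipped with a
    logged count. Chromosomes without any occupied bin are omitted.
    """
    bins_by_chrom = bin_genome(chrom_sizes, bin_size)
    unknown = sorted({p[0] for p in pm.peaks} - set(chrom_sizes))
    if unknown:
        n_unknown = sum(1 for p in pm.peaks if p[0] in set(unknown))
        logger.warning(
            "skipping %d peaks on %d chromosomes absent from chrom sizes: %s",
            n_unknown,
            len(unknown),
            ",".join(unknown[:5]),
        )
    out: dict[str, BinnedCellMatrix] = {}
    for chrom, bins in bins_by_chrom.items():
        merged, occupied = merge_peaks_into_bins(pm, bins)
        if not occupied:
            continue
        out[chrom] = BinnedCellMatrix(
            values=log_transform(merged),
            bins=occupied,
            cell_ids=list(pm.cell_ids),
            chrom=chrom,
            log_base="e",
            metadata={"bin_size": bin_size, "n_peaks_merged": merged.shape[1]},
        )
    return out
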