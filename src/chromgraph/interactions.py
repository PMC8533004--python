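"""Interaction calls from a fitted precision matrix, and their serialization.

A call is an off-diagonal bin pair whose partial correlation passes the
score filter. By default only positive partial correlations are called
(co-accessibility is a positive-association concept); ``sign_mode="both"``
keeps signed scores. Calls serialize to 10-column BEDPE and to a UCSC
interact-format track with |score| rescaled linearly from [0, 1] to
[0, 1000].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from chromgraph.graphical_model import EDGE_ZERO_TOL, PrecisionFit
from chromgraph.preprocess import GenomicBin


@dataclass(frozen=True)
class InteractionCall:
    """One predicted bin-pair interaction."""

    chrom: str
    bin_a: GenomicBin
    bin_b: GenomicBin
    score: float

    def __post_init__(self) -> None:
        if self.bin_a.chrom != self.chrom or self.bin_b.chrom != self.chrom:
            raise ValueError("both anchors must be on the call chromosome")
        if self.bin_a.start >= self.bin_b.start:
            raise ValueError("bin_a must precede bin_b")

    @property
    def distance(self) -> int:
        return self.bin_b.start - self.bin_a.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.bin_a.start}-{self.bin_b.start}"


def call_interactions(
    fit: PrecisionFit,
    bins: Sequence[GenomicBin],
    min_abs_score: float = 0.0,
    sign_mode: str = "positive",
    max_distance: int | None = None,
) -> list[InteractionCall]:
    """Threshold the partial-correlation matrix into interaction calls.

    ``max_distance`` caps the genomic span of a call (used to emulate
    window-limited methods); ``None`` means unlimited.
    """
    if min_abs_score < 0:
        raise ValueError("min_abs_score must be non-negative")
    if sign_mode not in ("positive", "both"):
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    pcor = fit.pcor
    p = pcor.shape[0]
    if p != len(bins):
        raise ValueError("bins must match fit dimension")
    chrom = bins[0].chrom
    calls: list[InteractionCall] = []
    threshold = max(min_abs_score, EDGE_ZERO_TOL)
    for i in range(p):
        for j in range(i + 1, p):
            score = float(pcor[i, j])
            if abs(score) <= threshold:
                continue
            if sign_mode == "positive" and score <= 0:
                continue
            a, b = bins[i], bins[j]
            if a.start > b.start:
                a, b = b, a
            if max_distance is not None and b.start - a.start > max_distance:
                continue
            calls.append(InteractionCall(chrom=chrom, bin_a=a, bin_b=b, score=score))
    calls.sort(key=lambda c: (c.bin_a.start, c.bin_b.start))
    return calls


def distance_stratified_counts(
    calls: Iterable[InteractionCall], boundaries: Sequence[int]
) -> list[int]:
    """Count calls per distance class.

    ``boundaries`` are strictly increasing bp cutoffs defining classes
    ``(0, b1], (b1, b2], ..., (b_last, inf)``, so a boundary of 500,000
    puts exactly the "more than 500 kbp" calls in the last class.
    """
    bounds = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("boundaries must be strictly increasing")
    counts = [0] * (len(bounds) + 1)
    for call in calls:
        counts[int(np.searchsorted(bounds, call.distance, side="left"))] += 1
    return counts


def write_bedpe(calls: Sequence[InteractionCall], path, header: str | None = None) -> None:
    """Write 10-column BEDPE: chrom1 start1 end1 chrom2 start2 end2 name score . .

    Scores are written with ``repr`` so a read/write round trip is exact.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.bin_a.start}\t{c.bin_a.end}\t"
                f"{c.chrom}\t{c.bin_b.start}\t{c.bin_b.end}\t"
                f"{c.name}\t{c.score!r}\t.\t.\n"
            )


def read_bedpe(path) -> list[InteractionCall]:
    """Read BEDPE written by :func:`write_bedpe` (comment lines ignored).

    Bin indices are reconstructed as ``start // bin_size`` where the bin
    size is the widest anchor in the file (truncated trailing bins are
    narrower than the nominal size).
    """
    rows: list[tuple[str, int, int, str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 BEDPE columns")
            chrom1, s1, e1, chrom2, s2, e2 = parts[:6]
            rows.append(
                (chrom1, int(s1), int(e1), chrom2, int(s2), int(e2), float(parts[7]))
            )
    if not rows:
        return []
    bin_size = max(max(r[2] - r[1], r[5] - r[4]) for r in rows)
    calls: list[InteractionCall] = []
    for chrom1, s1, e1, chrom2, s2, e2, score in rows:
        bin_a = GenomicBin(chrom1, s1, e1, s1 // bin_size)
        bin_b = GenomicBin(chrom2, s2, e2, s2 // bin_size)
        calls.append(InteractionCall(chrom=chrom1, bin_a=bin_a, bin_b=bin_b, score=score))
    return calls


def write_ucsc_track(
    calls: Sequence[InteractionCall],
    path,
    track_name: str = "chromgraph",
    header: str | None = None,
) -> None:
    """Write a UCSC interact-format track; |score| mapped linearly to 0-1000."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        fh.write(
            f'track type=interact name="{track_name}" '
            'description="predicted chromatin interactions; '
            'score = |partial correlation| * 1000" useScore=on\n'
        )
        for c in calls:
            ucsc_score = int(round(min(abs(c.score), 1.0) * 1000))
            fh.write(
                f"{c.chrom}\t{c.bin_a.start}\t{c.bin_b.end}\t{c.name}\t{ucsc_score}\t"
                f"{c.score!r}\t.\t0\t"
                f"{c.chrom}\t{c.bin_a.start}\t{c.bin_a.end}\t.\t.\t"
                f"{c.chrom}\t{c.bin_b.start}\t{c.bin_b.end}\t.\t.\n"
            )
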