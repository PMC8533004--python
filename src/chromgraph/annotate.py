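"""Paired-loci annotation of interaction calls and enrichment testing.

An interaction call supports a feature pair (e.g. an eQTL SNP and its
target gene's promoter) when one anchor bin overlaps a feature from the
left set and the other anchor overlaps a feature from the right set, in
either orientation. Overlap means non-empty interval intersection with the
full anchor bin. Enrichment of hit fractions between a case and a null
feature set is tested with a pooled two-proportion z-test; Benjamini-
Hochberg q-values are provided as a labelled extension for multi-set runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from chromgraph.interactions import InteractionCall
from chromgraph.preprocess import GenomicBin

logger = logging.getLogger(__name__)

CATEGORIES = ("eqtl-snp", "gene-promoter", "gwas-snp", "har")
LONG_RANGE_CUTOFF = 500_000


@dataclass(frozen=True)
class AnchorFeature:
    """A genomic feature intersected with interaction anchors (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    category: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid feature interval {self.chrom}:{self.start}-{self.end}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")

    def overlaps(self, bin_: GenomicBin) -> bool:
        return self.chrom == bin_.chrom and self.start < bin_.end and self.end > bin_.start


@dataclass
class PairedHit:
    """One call supported by features on both anchors."""

    interaction: InteractionCall
    left_features: list[AnchorFeature]
    right_features: list[AnchorFeature]
    orientation: str  # "forward": left on bin_a; "swapped": left on bin_b


@dataclass
class EnrichmentResult:
    enrichment: float  # NaN when the null fraction is 0
    z: float
    p: float
    defined: bool


def intersect_pairs(
    calls: Sequence[InteractionCall],
    left: Sequence[AnchorFeature],
    right: Sequence[AnchorFeature],
) -> list[PairedHit]:
    """Emit a hit per call with left features on one anchor and right on the other.

    Orientation is recorded; when both orientations match, the forward one
    is reported with the union of matching features per anchor.
    """
    hits: list[PairedHit] = []
    for call in calls:
        left_a = [f for f in left if f.overlaps(call.bin_a)]
        left_b = [f for f in left if f.overlaps(call.bin_b)]
        right_a = [f for f in right if f.overlaps(call.bin_a)]
        right_b = [f for f in right if f.overlaps(call.bin_b)]
        if left_a and right_b:
            hits.append(PairedHit(call, left_a, right_b, "forward"))
        elif left_b and right_a:
            hits.append(PairedHit(call, left_b, right_a, "swapped"))
    return hits


def long_range_hits(hits: Sequence[PairedHit], cutoff: int = LONG_RANGE_CUTOFF) -> list[PairedHit]:
    """Hits whose interaction spans more than ``cutoff`` bp."""
    return [h for h in hits if h.interaction.distance > cutoff]


def promoter_connectivity(
    calls: Sequence[InteractionCall], promoters: Sequence[AnchorFeature]
) -> dict[str, int]:
    """Per-gene count of calls with an anchor overlapping the gene's promoter.

    Promoter features carry gene names; duplicate names are merged (a call
    counts once per gene) with a warning.
    """
    names = [f.name for f in promoters]
    if len(set(names)) < len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        logger.warning("merging counts for duplicated gene names: %s", ",".join(dupes[:5]))
    by_gene: dict[str, list[AnchorFeature]] = {}
    for f in promoters:
        by_gene.setdefault(f.name, []).append(f)
    counts: dict[str, int] = {}
    for gene, feats in by_gene.items():
        touched = 0
        for call in calls:
            if any(f.overlaps(call.bin_a) or f.overlaps(call.bin_b) for f in feats):
                touched += 1
        counts[gene] = touched
    return counts


def relative_connectivity(
    counts_by_cell_type: Mapping[str, Mapping[str, int]]
) -> dict[str, dict[str, float]]:
    """Mean-center per-gene promoter connectivity across cell types."""
    genes = sorted({g for counts in counts_by_cell_type.values() for g in counts})
    out: dict[str, dict[str, float]] = {ct: {} for ct in counts_by_cell_type}
    for gene in genes:
        vals = {ct: counts.get(gene, 0) for ct, counts in counts_by_cell_type.items()}
        mean = sum(vals.values()) / len(vals)
        for ct, v in vals.items():
            out[ct][gene] = v - mean
    return out


def enrichment_two_proportion(
    hits_case: int, total_case: int, hits_null: int, total_null: int
) -> EnrichmentResult:
    """Enrichment ratio and pooled two-proportion z-test (two-sided).

    ``enrichment = (hits_case/total_case) / (hits_null/total_null)``;
    ``z = (p1 - p0) / sqrt(p_pool (1 - p_pool) (1/n1 + 1/n0))`` with the
    pooled proportion ``p_pool = (hits_case + hits_null) / (n1 + n0)``.
    A zero null fraction leaves the enrichment undefined (NaN, flagged).
    """
    if total_case <= 0 or total_null <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= hits_case <= total_case) or not (0 <= hits_null <= total_null):
        raise ValueError("hit counts must lie in [0, total]")
    p1 = hits_case / total_case
    p0 = hits_null / total_null
    pooled = (hits_case + hits_null) / (total_case + total_null)
    se = math.sqrt(pooled * (1 - pooled) * (1 / total_case + 1 / total_null))
    if se == 0.0:
        z = 0.0 if p1 == p0 else math.copysign(float("inf"), p1 - p0)
    else:
        z = (p1 - p0) / se
    p = float(2 * stats.norm.sf(abs(z)))
    if p0 == 0.0:
        logger.warning("null fraction is 0: enrichment ratio undefined")
        return EnrichmentResult(enrichment=float("nan"), z=z, p=p, defined=False)
    return EnrichmentResult(enrichment=p1 / p0, z=z, p=p, defined=True)


def bh_qvalues(pvals: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    pvals = np.asarray(list(pvals), dtype=float)
    n = len(pvals)
    if n == 0:
        return []
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q.tolist()
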