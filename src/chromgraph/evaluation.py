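"""Scoring of predicted interactions against contact-map positive sets.

Positive sets are the top-N most enriched contact-map entries, selected
either with a fixed N per chromosome (default 60,000) or with N allocated
proportionally to chromosome length so the longest chromosome gets exactly
N_max. Accuracy is the fraction of calls whose bin pair is in the positive
set, with bin-exact matching at the shared resolution (an optional slack of
+/-k bins is available for robustness studies).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from chromgraph.interactions import InteractionCall
from chromgraph.prior import ContactMap

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 60_000


@dataclass
class PositiveSet:
    """Top-enriched contact pairs used as evaluation truth."""

    chrom: str
    pairs: set[tuple[int, int]]
    scheme: str  # "per-chromosome-topN" | "proportional"
    n_requested: int
    n_selected: int


@dataclass
class AccuracyResult:
    accuracy: float  # NaN when undefined (no calls)
    n_calls: int
    n_matched: int
    defined: bool


def top_n_positive(cm: ContactMap, n: int = DEFAULT_TOP_N, scheme: str = "per-chromosome-topN") -> PositiveSet:
    """Select the ``n`` highest-valued off-diagonal pairs of a contact map.

    Ties at the cutoff break deterministically by (value desc, i asc, j asc).
    Diagonal entries are excluded (self-pairs are never predicted).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    items = [((i, j), v) for (i, j), v in cm.entries.items() if i != j]
    items.sort(key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    chosen = {key for key, _ in items[:n]}
    return PositiveSet(
        chrom=cm.chrom,
        pairs=chosen,
        scheme=scheme,
        n_requested=n,
        n_selected=len(chosen),
    )


def proportional_n(chrom_sizes: Mapping[str, int], n_max: int = DEFAULT_TOP_N) -> dict[str, int]:
    """Allocate per-chromosome N proportional to length.

    ``n(chrom) = round(n_max * length / max_length)``; the longest
    chromosome gets exactly ``n_max``. Rounding is half-up for determinism.
    """
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    if not chrom_sizes:
        raise ValueError("empty chrom sizes")
    longest = max(chrom_sizes.values())
    return {
        chrom: int(math.floor(n_max * length / longest + 0.5))
        for chrom, length in chrom_sizes.items()
    }


def overlap_accuracy(
    calls: Sequence[InteractionCall], pos: PositiveSet, slack_bins: int = 0
) -> AccuracyResult:
    """Fraction of calls whose (bin_a, bin_b) pair is in the positive set.

    With ``slack_bins=k`` a call matches if any pair within +/-k bins of
    both anchors is positive. Zero calls leaves accuracy undefined (NaN,
    flagged), never silently 0.
    """
    if not calls:
        logger.warning("no calls: overlap accuracy is undefined")
        return AccuracyResult(accuracy=float("nan"), n_calls=0, n_matched=0, defined=False)
    n_matched = 0
    offsets = range(-slack_bins, slack_bins + 1)
    for call in calls:
        i, j = call.bin_a.index, call.bin_b.index
        if slack_bins == 0:
            hit = (i, j) in pos.pairs or (j, i) in pos.pairs
        else:
            hit = any(
                (min(i + di, j + dj), max(i + di, j + dj)) in pos.pairs
                for di in offsets
                for dj in offsets
            )
        if hit:
            n_matched += 1
    return AccuracyResult(
        accuracy=n_matched / len(calls),
        n_calls=len(calls),
        n_matched=n_matched,
        defined=True,
    )


def edge_recovery_auprc(
    score_matrix: np.ndarray, true_edges: Iterable[tuple[int, int]]
) -> float:
    """Area under the precision-recall curve for edge recovery.

    Scores are |off-diagonal| entries of ``score_matrix`` (upper triangle);
    labels are membership in ``true_edges``.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    p = score_matrix.shape[0]
    truth = {(min(i, j), max(i, j)) for i, j in true_edges}
    iu, ju = np.triu_indices(p, k=1)
    scores = np.abs(score_matrix[iu, ju])
    labels = np.array([(i, j) in truth for i, j in zip(iu, ju)], dtype=int)
    if labels.sum() == 0:
        raise ValueError("no true edges among the scored pairs")
    return float(average_precision_score(labels, scores))
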