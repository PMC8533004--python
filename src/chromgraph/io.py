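"""Shared readers and writers for the pipeline's text formats.

All readers are gzip-transparent (paths ending in ``.gz``). Formats:
chrom.sizes (two-column), BED features, dense TSV or matrix-market peak
matrices, and the juicer-style three-column contact dump with its
seven-column paired-loci conversion.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from chromgraph.annotate import AnchorFeature
from chromgraph.preprocess import PeakCountMatrix

logger = logging.getLogger(__name__)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column (name, length) chrom.sizes file."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected name and length")
            sizes[parts[0]] = int(parts[1])
    if not sizes:
        raise ValueError(f"{path}: no chromosomes found")
    return sizes


def load_bed_peaks(path) -> list[tuple[str, int, int, str]]:
    """Read peak intervals from BED (0-based half-open); name defaults to coords."""
    peaks: list[tuple[str, int, int, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            peaks.append((chrom, start, end, name))
    return peaks


def load_bed_features(path, category: str) -> list[AnchorFeature]:
    """Read BED intervals as :class:`AnchorFeature` of one category."""
    feats = []
    for chrom, start, end, name in load_bed_peaks(path):
        feats.append(AnchorFeature(chrom=chrom, start=start, end=end, name=name, category=category))
    return feats


def load_peak_matrix(
    matrix_path,
    peaks_path=None,
    cells_path=None,
    fmt: str = "auto",
    orientation: str = "cells-by-peaks",
) -> PeakCountMatrix:
    """Load a peak count matrix.

    ``fmt="dense"``: TSV with cell ids in the first column and peak ids
    (``chrom:start-end``) as the header, or the transpose with
    ``orientation="peaks-by-cells"``. ``fmt="mtx"``: matrix-market triplets
    plus a BED peak file and an optional one-per-line cell-id list.
    ``fmt="auto"`` picks ``mtx`` for ``.mtx``/``.mtx.gz`` suffixes.
    """
    if orientation not in ("cells-by-peaks", "peaks-by-cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    name = str(matrix_path)
    if fmt == "auto":
        fmt = "mtx" if name.endswith((".mtx", ".mtx.gz")) else "dense"

    if fmt == "mtx":
        if peaks_path is None:
            raise ValueError("mtx input requires a BED peak file")
        mat = np.asarray(mmread(str(matrix_path)).todense())
        if orientation == "peaks-by-cells":
            mat = mat.T
        peaks = load_bed_peaks(peaks_path)
        if cells_path is not None:
            with _open_text(cells_path) as fh:
                cell_ids = [ln.strip() for ln in fh if ln.strip()]
        else:
            cell_ids = [f"cell{i}" for i in range(mat.shape[0])]
        return PeakCountMatrix(counts=mat, peaks=peaks, cell_ids=cell_ids)

    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if orientation == "peaks-by-cells":
        df = df.T
    if peaks_path is not None:
        peaks = load_bed_peaks(peaks_path)
        if len(peaks) != df.shape[1]:
            raise ValueError(
                f"{len(peaks)} peaks in BED but {df.shape[1]} matrix columns"
            )
    else:
        peaks = [_parse_peak_id(c) for c in df.columns]
    return PeakCountMatrix(
        counts=df.to_numpy(),
        peaks=peaks,
        cell_ids=[str(i) for i in df.index],
    )


def _parse_peak_id(peak_id: str) -> tuple[str, int, int, str]:
    """Parse ``chrom:start-end`` (or chrom_start_end) peak column labels."""
    peak_id = str(peak_id)
    try:
        if ":" in peak_id:
            chrom, rest = peak_id.split(":", 1)
            start, end = rest.replace("-", " ").split()
        else:
            chrom, start, end = peak_id.rsplit("_", 2)
        return chrom, int(start), int(end), peak_id
    except ValueError as exc:
        raise ValueError(
            f"cannot parse peak id {peak_id!r}; expected chrom:start-end "
            "(or pass an explicit peak BED file)"
        ) from exc


def write_dense_matrix(counts: np.ndarray, peak_ids, cell_ids, path) -> None:
    """Write a cells x peaks TSV readable by :func:`load_peak_matrix`."""
    df = pd.DataFrame(np.asarray(counts), index=list(cell_ids), columns=list(peak_ids))
    df.to_csv(path, sep="\t")


def hic_text_to_pgl(path_in, resolution: int, path_out, chrom: str) -> int:
    """Convert a 3-column contact dump to 7-column paired-loci text.

    Output rows: chrom start1 end1 chrom start2 end2 value, with
    ``end = start + resolution``. Returns the number of lines written
    (equal to the number of data lines read).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = 0
    with _open_text(path_in) as src, open(path_out, "w") as dst:
        for lineno, line in enumerate(src, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path_in}:{lineno}: expected 3 columns")
            try:
                s1, s2 = int(parts[0]), int(parts[1])
                float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path_in}:{lineno}: malformed line: {line!r}") from exc
            dst.write(
                f"{chrom}\t{s1}\t{s1 + resolution}\t{chrom}\t{s2}\t{s2 + resolution}\t{parts[2]}\n"
            )
            n += 1
    return n


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
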