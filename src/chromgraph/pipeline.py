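"""End-to-end orchestration: counts -> bins -> (impute) -> penalty -> fit -> calls.

The graphical model is estimated independently per chromosome. Outputs are
a merged BEDPE, a UCSC interact track and a JSON run report; every output
carries a header with the tool version and a hash of the serialized
configuration, so identical configurations produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import chromgraph
from chromgraph import io as cgio
from chromgraph.graphical_model import empirical_covariance, fit_glasso
from chromgraph.impute import mm_factorize, default_rank
from chromgraph.interactions import call_interactions, write_bedpe, write_ucsc_track
from chromgraph.preprocess import bin_matrix, DEFAULT_BIN_SIZE
from chromgraph.prior import (
    average_contacts,
    build_penalty,
    constant_penalty,
    load_contact_text,
    DEFAULT_CONSTANT_RHO,
    DEFAULT_DELTA,
    DEFAULT_EPS,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one prediction run."""

    matrix: str
    chrom_sizes: str
    out_dir: str
    peaks: str | None = None
    cells: str | None = None
    matrix_format: str = "auto"
    orientation: str = "cells-by-peaks"
    bin_size: int = DEFAULT_BIN_SIZE
    hic: list[str] = field(default_factory=list)  # "path" or "chrom=path"
    delta: float = DEFAULT_DELTA
    eps: float = DEFAULT_EPS
    log_scale_prior: bool = False
    constant_rho: float | None = None  # set to use the constant baseline
    impute: bool = True
    rank: int | None = None
    mm_iters: int = 200
    mm_tol: float = 1e-5
    mask_zeros: bool = False
    mm_a: float = 1.0
    tol: float = 1e-4
    max_iter: int = 100
    min_abs_score: float = 0.0
    sign_mode: str = "positive"
    max_distance: int | None = None
    seed: int = 0
    force: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.eps <= 0 or self.delta <= 0:
            raise ValueError("delta and eps must be positive")
        if self.constant_rho is not None and self.constant_rho < 0:
            raise ValueError("constant_rho must be non-negative")
        if self.min_abs_score < 0:
            raise ValueError("min_abs_score must be non-negative")
        if self.sign_mode not in ("positive", "both"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")
        if self.constant_rho is None and not self.hic:
            raise ValueError("provide at least one --hic contact map or --constant-rho")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and
        overwrite policy excluded, so reruns elsewhere hash identically)."""
        payload = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "force")}
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _hic_paths_for(config: RunConfig, chrom: str) -> list[str]:
    paths = []
    for entry in config.hic:
        if "=" in entry:
            target, path = entry.split("=", 1)
            if target == chrom:
                paths.append(path)
        else:
            paths.append(entry)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run the full prediction pipeline; returns the run report dict."""
    out_dir = cgio.ensure_dir(config.out_dir)
    bedpe_path = out_dir / "predictions.bedpe"
    if bedpe_path.exists() and not config.force:
        raise FileExistsError(f"{bedpe_path} exists; re-run with force=True to overwrite")

    header = f"chromgraph v{chromgraph.__version__} config={config.config_hash()}"
    t0 = time.time()
    chrom_sizes = cgio.load_chrom_sizes(config.chrom_sizes)
    pm = cgio.load_peak_matrix(
        config.matrix,
        peaks_path=config.peaks,
        cells_path=config.cells,
        fmt=config.matrix_format,
        orientation=config.orientation,
    )
    binned = bin_matrix(pm, chrom_sizes, config.bin_size)

    all_calls = []
    report_chroms = {}
    for chrom in sorted(binned):
        t_chrom = time.time()
        bcm = binned[chrom]
        X = bcm.values
        logger.info("%s: %d cells x %d occupied bins", chrom, X.shape[0], X.shape[1])

        impute_info = None
        if config.impute and min(X.shape) >= 3:
            rank = config.rank or default_rank(*X.shape)
            rank = min(rank, min(X.shape) - 1)
            mask = (X > 0).astype(float) if config.mask_zeros else None
            res = mm_factorize(
                X, A=mask, r=rank, a=config.mm_a,
                max_iter=config.mm_iters, tol=config.mm_tol,
            )
            X = res.X
            impute_info = {
                "rank": rank,
                "n_iter": res.n_iter,
                "converged": res.converged,
                "final_cost": res.cost_trace[-1],
            }

        cov = empirical_covariance(X)
        if config.constant_rho is not None:
            penalty = constant_penalty(len(bcm.bins), config.constant_rho)
        else:
            paths = _hic_paths_for(config, chrom)
            if not paths:
                logger.warning("%s: no contact map provided; skipping chromosome", chrom)
                continue
            maps = [
                load_contact_text(p, config.bin_size, chrom=chrom) for p in paths
            ]
            h_avg = average_contacts(maps)
            penalty = build_penalty(
                h_avg, bcm.bins, delta=config.delta, eps=config.eps,
                log_scale=config.log_scale_prior,
            )

        fit = fit_glasso(cov, penalty, tol=config.tol, max_iter=config.max_iter)
        calls = call_interactions(
            fit,
            bcm.bins,
            min_abs_score=config.min_abs_score,
            sign_mode=config.sign_mode,
            max_distance=config.max_distance,
        )
        all_calls.extend(calls)
        report_chroms[chrom] = {
            "n_cells": int(bcm.n_cells),
            "n_bins": int(bcm.n_bins),
            "n_edges": fit.n_edges,
            "n_calls": len(calls),
            "converged": bool(fit.converged),
            "n_sweeps": fit.n_iter,
            "objective_first": fit.objective_trace[0],
            "objective_last": fit.objective_trace[-1],
            "penalty_mode": penalty.mode,
            "impute": impute_info,
            "seconds": round(time.time() - t_chrom, 3),
        }

    all_calls.sort(key=lambda c: (c.chrom, c.bin_a.start, c.bin_b.start))
    write_bedpe(all_calls, bedpe_path, header=header)
    write_ucsc_track(all_calls, out_dir / "predictions.interact", header=header)

    report = {
        "tool": "chromgraph",
        "version": chromgraph.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_calls": len(all_calls),
        "chromosomes": report_chroms,
        "seconds": round(time.time() - t0, 3),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
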