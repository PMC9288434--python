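"""Cell/gene filtering and per-cell log-normalization.

Filter order in the pipeline is fixed: genes first (drop genes not
detected in more than ``min_cells`` cells, with seed-panel genes exempt),
then cells (drop cells detecting fewer than ``min_genes`` genes).  The
pair is idempotent.  "Detected" always means raw count > 0.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ExpressionBundle, SeedPanel

log = logging.getLogger("hemorank")


class PreprocessError(ValueError):
    pass


def detection_mask(bundle: ExpressionBundle) -> np.ndarray:
    """Boolean cells x genes matrix, True where raw count > 0."""
    return bundle.counts_dense() > 0


def filter_genes(bundle: ExpressionBundle, min_cells: int,
                 panel: SeedPanel | None = None) -> ExpressionBundle:
    """Keep gene g iff detected in strictly more than ``min_cells`` cells.

    Seed-panel genes are exempt: a low-frequency TF (e.g. Runx1 in a small
    tissue) must never be silently dropped before frequency analysis.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    detected = np.asarray((bundle.counts > 0).sum(axis=0)).ravel()
    keep = detected > min_cells
    if panel is not None:
        seed_set = set(panel.seed_tfs)
        rescued = [g for g, k in zip(bundle.gene_ids, keep)
                   if not k and g in seed_set]
        if rescued:
            log.info("gene filter: rescued seed-panel genes %s", rescued)
        keep |= np.array([g in seed_set for g in bundle.gene_ids])
    if not keep.any():
        raise PreprocessError("gene filter would remove all genes")
    return bundle.subset(gene_mask=keep)


class CellFilterResult(NamedTuple):
    bundle: ExpressionBundle
    detected_per_cell: pd.Series  # pre-filter histogram input, all cells


def filter_cells(bundle: ExpressionBundle, min_genes: int) -> CellFilterResult:
    """Keep cell c iff it detects at least ``min_genes`` genes.

    Also returns the per-cell detected-gene counts so the threshold can be
    chosen by inspecting their histogram.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    detected = np.asarray((bundle.counts > 0).sum(axis=1)).ravel()
    per_cell = pd.Series(detected, index=list(bundle.cell_ids), name="n_genes_detected")
    keep = detected >= min_genes
    if not keep.any():
        raise PreprocessError("cell filter would remove all cells")
    return CellFilterResult(bundle.subset(cell_mask=keep), per_cell)


def lognormalize(bundle: ExpressionBundle, scale: float = 10_000.0) -> ExpressionBundle:
    """Global-scaling log-normalization.

    normalized(c, g) = ln(1 + count(c, g) / total(c) * scale); the counts
    layer is preserved unchanged.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = np.asarray(bundle.counts.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise PreprocessError(
            "cells with zero total counts present; run filter_cells first")
    norm = bundle.counts.tocoo(copy=True).astype(float)
    norm.data = np.log1p(norm.data / totals[norm.row] * scale)
    return ExpressionBundle(
        counts=bundle.counts,
        gene_ids=bundle.gene_ids,
        cell_ids=bundle.cell_ids,
        cell_meta=bundle.cell_meta,
        normalized=sp.csr_matrix(norm),
    )


def preprocess(bundle: ExpressionBundle, config, panel: SeedPanel | None = None):
    """Standard sequence: gene filter -> cell filter -> log-normalize."""
    bundle = filter_genes(bundle, config.filter_min_cells_per_gene, panel)
    bundle, _ = filter_cells(bundle, config.filter_min_genes_per_cell)
    return lognormalize(bundle, config.lognorm_scale)
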