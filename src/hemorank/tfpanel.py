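"""Seed-TF expression frequency and single-cell co-expression statistics.

For every (tissue, population) group this module reports, per seed TF,
the detection fraction (cells with count > 0) and the mean normalized
expression among expressing cells -- the two quantities a dot plot shows --
and the distribution of the per-cell number of co-detected panel TFs,
summarized by the largest k such that at least half the cells co-express
at least k TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionBundle, SeedPanel
from .preprocess import detection_mask

log = logging.getLogger("hemorank")

GROUP_COLS = ["tissue", "population"]


def tf_frequency(bundle: ExpressionBundle, panel: SeedPanel) -> pd.DataFrame:
    """Per (tissue, population, tf): detection fraction, mean expression in
    expressing cells, cell count and moderate/low frequency class."""
    if bundle.normalized is None:
        raise ValueError("normalized layer required; run lognormalize first")
    tf_idx = bundle.gene_index(panel.seed_tfs)
    mask = detection_mask(bundle)[:, tf_idx]
    norm = bundle.normalized_dense()[:, tf_idx]
    rows = []
    for keys, idx in bundle.cell_meta.groupby(GROUP_COLS, sort=True).groups.items():
        pos = bundle.cell_meta.index.get_indexer(idx)
        n = len(pos)
        if n == 0:
            log.warning("tf_frequency: empty group %s omitted", keys)
            continue
        for j, tf in enumerate(panel.seed_tfs):
            det = mask[pos, j]
            frac = det.mean()
            mean_expr = norm[pos, j][det].mean() if det.any() else 0.0
            rows.append({
                "tissue": keys[0], "population": keys[1], "tf": tf,
                "detect_fraction": float(frac),
                "mean_expr_in_expressing": float(mean_expr),
                "n_cells": n,
                "freq_class": "moderate" if frac > panel.moderate_freq_threshold
                              else "low",
            })
    return pd.DataFrame(rows)


def coexpression_counts(mask: np.ndarray, subset_idx: np.ndarray) -> np.ndarray:
    """Per-cell number of sub-panel TFs detected (k)."""
    return np.asarray(mask)[:, subset_idx].sum(axis=1).astype(int)


@dataclass
class CoexpressionDistribution:
    """Exact per-group distribution of the per-cell co-expression count k."""

    k_max: int
    table: pd.DataFrame  # tissue, population, k, count, fraction_at_least_k

    def group(self, tissue: str, population: str) -> pd.DataFrame:
        t = self.table
        return t[(t.tissue == tissue) & (t.population == population)]

    def fraction_at_least(self, tissue: str, population: str, k: int) -> float:
        g = self.group(tissue, population)
        row = g[g.k == k]
        return float(row.fraction_at_least_k.iloc[0]) if len(row) else 0.0

    def k_star(self, tissue: str, population: str) -> int:
        """Largest k with fraction_at_least_k >= 0.5 (the headline summary)."""
        g = self.group(tissue, population)
        ok = g[g.fraction_at_least_k >= 0.5]
        return int(ok.k.max()) if len(ok) else 0

    def mean_fraction_coexpressed(self, tissue: str, population: str) -> float:
        """Mean per-cell k divided by the panel size K."""
        g = self.group(tissue, population)
        n = g["count"].sum()
        if n == 0 or self.k_max == 0:
            return 0.0
        return float((g.k * g["count"]).sum() / n / self.k_max)


def coexpression_distribution(k_values: np.ndarray, cell_meta: pd.DataFrame,
                              k_max: int) -> CoexpressionDistribution:
    """Exact counts and at-least-k fractions per (tissue, population)."""
    k_values = np.asarray(k_values)
    rows = []
    for keys, idx in cell_meta.groupby(GROUP_COLS, sort=True).groups.items():
        pos = cell_meta.index.get_indexer(idx)
        ks = k_values[pos]
        n = len(ks)
        counts = np.bincount(ks, minlength=k_max + 1)
        at_least = counts[::-1].cumsum()[::-1] / n
        for k in range(k_max + 1):
            rows.append({"tissue": keys[0], "population": keys[1], "k": k,
                         "count": int(counts[k]),
                         "fraction_at_least_k": float(at_least[k])})
    return CoexpressionDistribution(k_max=k_max, table=pd.DataFrame(rows))


def panel_coexpression(bundle: ExpressionBundle, panel: SeedPanel,
                       full_panel: bool = False) -> CoexpressionDistribution:
    """Co-expression distribution over the sub-panel (default) or, because
    published summaries sometimes count the full panel, over all seed TFs."""
    genes = panel.seed_tfs if full_panel else panel.coexpr_subset
    idx = bundle.gene_index(genes)
    k = coexpression_counts(detection_mask(bundle), idx)
    return coexpression_distribution(k, bundle.cell_meta, k_max=len(genes))
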