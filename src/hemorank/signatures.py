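"""Target-set overlap analysis and Runx1+ signature recurrence.

Pairwise overlap between the per-TF target sets of one tissue's network
quantifies whether the seed TFs co-regulate a shared program; the
"clique" is the largest TF subset in which every pair shares at least
half of each other's targets (reciprocal fraction >= 0.5), found by
exhaustive subset search (at most 2^11 subsets).

Runx1+ signatures: endothelial cells expressing Runx1 are split into a
separate group and contrasted against the remaining endothelium with a
two-sided rank-sum test plus a log fold-change gate; markers recurring in
at least ``min_tissues`` tissues form the cross-tissue Runx1+ signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .activity import holm_adjust
from .core_io import ExpressionBundle

log = logging.getLogger("hemorank")


class SplitError(ValueError):
    """The TF+/TF- split is degenerate (one side too small)."""


# ---------------------------------------------------------------------------
# Pairwise overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapMatrix:
    tfs: list[str]
    count: pd.DataFrame   # symmetric intersection counts, count[i][j] = |T_i & T_j|
    frac: pd.DataFrame    # row-normalized: frac.loc[i, j] = |T_i & T_j| / |T_j|
    clique_tfs: list[str] = field(default_factory=list)
    empty_tfs: list[str] = field(default_factory=list)

    def pair_count(self, a: str, b: str) -> int:
        return int(self.count.loc[a, b])

    def pair_frac(self, a: str, b: str) -> float:
        return float(self.frac.loc[a, b])


def pairwise_overlap(target_sets: dict[str, set], clique_frac: float = 0.5) -> OverlapMatrix:
    """Intersection counts, row-normalized fractions and the high-overlap
    clique of the given per-TF target sets."""
    tfs = list(target_sets)
    if len(tfs) < 2:
        raise ValueError("need >= 2 target sets")
    sets = {tf: set(target_sets[tf]) for tf in tfs}
    empty = [tf for tf in tfs if not sets[tf]]
    if empty:
        log.info("pairwise_overlap: empty target sets for %s", empty)
    count = pd.DataFrame(0, index=tfs, columns=tfs, dtype=int)
    frac = pd.DataFrame(0.0, index=tfs, columns=tfs)
    for a in tfs:
        for b in tfs:
            c = len(sets[a] & sets[b])
            count.loc[a, b] = c
            frac.loc[a, b] = c / len(sets[b]) if sets[b] else 0.0

    nonempty = [tf for tf in tfs if sets[tf]]
    best: tuple[str, ...] = ()
    for size in range(len(nonempty), 1, -1):
        for combo in combinations(nonempty, size):
            ok = all(frac.loc[a, b] >= clique_frac and frac.loc[b, a] >= clique_frac
                     for a, b in combinations(combo, 2))
            if ok:
                best = combo
                break
        if best:
            break
    return OverlapMatrix(tfs=tfs, count=count, frac=frac,
                         clique_tfs=list(best), empty_tfs=empty)


# ---------------------------------------------------------------------------
# Runx1+ split and markers
# ---------------------------------------------------------------------------

def split_by_tf(bundle: ExpressionBundle, tissue: str, population: str = "endothelial",
                tf: str = "Runx1", min_group: int = 3) -> pd.Series:
    """Label the population's cells 'tf_pos' (count > 0) vs 'tf_neg'.

    Raises :class:`SplitError` when either side has fewer than
    ``min_group`` cells -- e.g. a tissue with no TF-expressing endothelium.
    """
    mask = ((bundle.cell_meta["tissue"] == tissue) &
            (bundle.cell_meta["population"] == population)).to_numpy()
    if not mask.any():
        raise SplitError(f"no {population} cells in tissue {tissue!r}")
    gi = bundle.gene_index([tf])[0]
    expr = np.asarray(bundle.counts[mask, gi].todense()).ravel()
    labels = np.where(expr > 0, "tf_pos", "tf_neg")
    n_pos = int((labels == "tf_pos").sum())
    n_neg = len(labels) - n_pos
    if n_pos < min_group:
        raise SplitError(
            f"{tissue}: no (or too few, {n_pos}) {tf}+ {population} cells")
    if n_neg < min_group:
        raise SplitError(
            f"{tissue}: too few {tf}- {population} cells ({n_neg})")
    return pd.Series(labels, index=bundle.cell_meta.index[mask], name="group")


def marker_genes(bundle: ExpressionBundle, labels: pd.Series, alpha: float = 0.05,
                 lfc_threshold: float = 0.25) -> pd.DataFrame:
    """Rank-sum markers of the 'tf_pos' group vs 'tf_neg'.

    Per gene: two-sided Mann-Whitney test on normalized values plus the
    log fold-change (difference of mean normalized, i.e. log-space)
    between groups; markers satisfy Holm-adjusted p < alpha and
    lfc > ``lfc_threshold`` in the positive group.
    """
    if bundle.normalized is None:
        raise ValueError("normalized layer required")
    pos_ids = labels.index[labels == "tf_pos"]
    neg_ids = labels.index[labels == "tf_neg"]
    if len(pos_ids) < 3 or len(neg_ids) < 3:
        raise SplitError("both groups must have >= 3 cells")
    id_pos = {c: i for i, c in enumerate(bundle.cell_ids)}
    pos_rows = np.array([id_pos[c] for c in pos_ids])
    neg_rows = np.array([id_pos[c] for c in neg_ids])
    norm = bundle.normalized_dense()
    a = norm[pos_rows]
    b = norm[neg_rows]
    n_genes = norm.shape[1]
    pvals = np.ones(n_genes)
    for j in range(n_genes):
        x, y = a[:, j], b[:, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            continue  # identical constant distributions: p = 1
        pvals[j] = scipy.stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    lfc = a.mean(axis=0) - b.mean(axis=0)
    holm = holm_adjust(pvals, alpha)
    out = pd.DataFrame({
        "gene": bundle.gene_ids,
        "p": pvals,
        "p_adj": holm.p_adj,
        "lfc": lfc,
        "is_marker": (holm.p_adj < alpha) & (lfc > lfc_threshold),
    })
    return out.sort_values(["is_marker", "p_adj"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Recurrence
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceTable:
    gene_tissues: pd.Series     # gene -> frozenset of tissues
    recurrent_genes: list[str]  # present in >= min_tissues tissues
    min_tissues: int


def recurrence(marker_lists: dict[str, list], min_tissues: int) -> RecurrenceTable:
    """Genes appearing as markers in at least ``min_tissues`` tissues."""
    if len(marker_lists) < min_tissues:
        raise ValueError(
            f"only {len(marker_lists)} tissues supplied, need >= {min_tissues}")
    gene_tissues: dict[str, set] = {}
    for tissue, genes in marker_lists.items():
        for g in set(genes):
            gene_tissues.setdefault(g, set()).add(tissue)
    series = pd.Series({g: frozenset(t) for g, t in gene_tissues.items()},
                       name="tissues")
    recurrent = sorted(g for g, t in gene_tissues.items() if len(t) >= min_tissues)
    return RecurrenceTable(gene_tissues=series, recurrent_genes=recurrent,
                           min_tissues=min_tissues)
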