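"""Per-cell target-set activity: rankings, recovery-curve AUC, thresholds,
and Kruskal--Wallis significance with Holm--Bonferroni correction.

Each cell's genes are ranked from highest to lowest normalized expression
(ties, including the zero block, broken by a seeded random shuffle).  For
a target-gene set, the recovery curve walks the top ``top_fraction`` of
the ranking counting cumulative set hits; its area, normalized by the
maximum achievable, is the cell's activity score in [0, 1].  A
two-component Gaussian mixture locates the threshold between inactive and
active score modes.  Significance per cell comes from a two-group
Kruskal--Wallis test of set vs background rank values, Holm-corrected
across cells; a cell is assigned to a target set when it passes both the
threshold and the significance gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats
from sklearn.mixture import GaussianMixture

log = logging.getLogger("hemorank")


# ---------------------------------------------------------------------------
# Holm--Bonferroni
# ---------------------------------------------------------------------------

@dataclass
class HolmResult:
    significant: np.ndarray  # bool flags, input order
    p_adj: np.ndarray        # monotone step-down adjusted p-values


def holm_adjust(p_values, alpha: float = 0.05) -> HolmResult:
    """Step-down Holm procedure.

    Sorted p(i) is compared to alpha/(m-i+1); the first failure stops the
    procedure and all later hypotheses are non-significant.  Adjusted
    p-values are the standard monotone max_{j<=i} (m-j+1)*p(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    sig = np.zeros(m, dtype=bool)
    p_adj = np.ones(m)
    if m == 0:
        return HolmResult(sig, p_adj)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    factors = m - np.arange(m)
    adj_sorted = np.minimum(np.maximum.accumulate(factors * sorted_p), 1.0)
    thresholds = alpha / factors
    passing = sorted_p < thresholds
    # step-down: stop at first failure
    first_fail = np.argmax(~passing) if (~passing).any() else m
    sig_sorted = np.zeros(m, dtype=bool)
    sig_sorted[:first_fail] = True
    sig[order] = sig_sorted
    p_adj[order] = adj_sorted
    return HolmResult(sig, p_adj)


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

@dataclass
class RankingMatrix:
    ranks: np.ndarray          # cells x genes, each row a permutation of 1..G
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    tie_seed: int

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[1]


def build_rankings(values: np.ndarray, gene_ids, cell_ids, seed: int = 0) -> RankingMatrix:
    """Per-cell gene ranking, 1 = highest value; ties (and hence the zero
    block) are randomly ordered, reproducibly under ``seed``."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(values.shape)
    ranks = np.empty_like(values, dtype=np.int64)
    cols = np.arange(1, n_genes + 1)
    for i in range(n_cells):
        order = np.lexsort((tiebreak[i], -values[i]))
        ranks[i, order] = cols
    return RankingMatrix(ranks=ranks, gene_ids=np.asarray(gene_ids, dtype=object),
                         cell_ids=np.asarray(cell_ids, dtype=object), tie_seed=seed)


# ---------------------------------------------------------------------------
# Recovery-curve AUC
# ---------------------------------------------------------------------------

def auc_score(rankings: RankingMatrix, gene_set, top_fraction: float = 0.05) -> np.ndarray:
    """Recovery-curve AUC per cell, in [0, 1].

    With L = floor(top_fraction * n_genes), the curve value at rank r is
    the number of set genes at rank <= r; the raw area sums the curve over
    r = 1..L and is normalized by its maximum (the whole set, capped at L,
    occupying ranks 1..min(|set|, L)).
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    present = set(rankings.gene_ids)
    inside = [g for g in gene_set if g in present]
    if not inside:
        raise ValueError(f"gene set has no genes in the ranking: missing {gene_set}")
    L = int(np.floor(top_fraction * rankings.n_genes))
    if L < 1:
        raise ValueError("top_fraction * n_genes < 1; nothing to scan")
    lookup = {g: i for i, g in enumerate(rankings.gene_ids)}
    idx = np.array([lookup[g] for g in inside])
    set_ranks = rankings.ranks[:, idx]  # cells x k
    contrib = np.clip(L - set_ranks + 1, 0, None)  # (L - s + 1) for s <= L
    raw = contrib.sum(axis=1).astype(float)
    k_eff = min(len(inside), L)
    max_raw = float(sum(L - i + 1 for i in range(1, k_eff + 1)))
    return raw / max_raw


# ---------------------------------------------------------------------------
# Threshold exploration
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    threshold: float
    bimodal: bool
    means: tuple[float, float] | None = None
    sds: tuple[float, float] | None = None


def explore_threshold(auc_values, seed: int = 0, min_cells: int = 50,
                      fallback_percentile: float = 99.0) -> ThresholdResult:
    """Bimodality-based threshold on an AUC distribution.

    A two-component Gaussian mixture is fitted; when the component means
    are separated by more than twice the pooled SD, the threshold is the
    equal-posterior point between them.  Otherwise (unimodal or
    degenerate) the global ``fallback_percentile`` percentile is used and
    flagged.
    """
    auc = np.asarray(auc_values, dtype=float).ravel()
    if len(auc) < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {len(auc)}")
    fallback = float(np.percentile(auc, fallback_percentile))
    if auc.std() < 1e-12:
        return ThresholdResult(threshold=fallback, bimodal=False)
    gm = GaussianMixture(n_components=2, n_init=5, reg_covar=1e-8,
                         random_state=int(seed) % (2 ** 31))
    gm.fit(auc.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(means)
    pooled = float(np.sqrt((sds[lo] ** 2 + sds[hi] ** 2) / 2.0))
    if means[hi] - means[lo] <= 2.0 * pooled or pooled < 1e-12:
        return ThresholdResult(threshold=fallback, bimodal=False)

    w = gm.weights_

    def posterior_diff(x):
        d_lo = w[lo] * scipy.stats.norm.pdf(x, means[lo], sds[lo])
        d_hi = w[hi] * scipy.stats.norm.pdf(x, means[hi], sds[hi])
        return d_hi - d_lo

    try:
        thr = float(scipy.optimize.brentq(posterior_diff, means[lo], means[hi]))
    except ValueError:
        thr = float((means[lo] + means[hi]) / 2.0)
    return ThresholdResult(threshold=thr, bimodal=True,
                           means=(float(means[lo]), float(means[hi])),
                           sds=(float(sds[lo]), float(sds[hi])))


# ---------------------------------------------------------------------------
# Kruskal--Wallis significance
# ---------------------------------------------------------------------------

def kw_significance(rankings: RankingMatrix, gene_set, alpha: float = 0.05):
    """Per-cell two-group Kruskal--Wallis test of set vs background ranks.

    Because each cell's ranks are an exact permutation of 1..G there are
    no ties, and the two-group statistic has the closed form
    H = 12/(G(G+1)) * sum_i n_i (Rbar_i - (G+1)/2)^2 with a chi-square(1)
    null.  Returns (p, HolmResult) with Holm correction across cells.
    """
    gene_set = list(dict.fromkeys(gene_set))
    lookup = {g: i for i, g in enumerate(rankings.gene_ids)}
    idx = np.array([lookup[g] for g in gene_set if g in lookup])
    G = rankings.n_genes
    n1 = len(idx)
    n2 = G - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("set and background must both contain >= 2 genes")
    grand = (G + 1) / 2.0
    r1 = rankings.ranks[:, idx].mean(axis=1)
    total = G * grand
    r2 = (total - r1 * n1) / n2
    h = 12.0 / (G * (G + 1)) * (n1 * (r1 - grand) ** 2 + n2 * (r2 - grand) ** 2)
    p = scipy.stats.chi2.sf(h, df=1)
    return p, holm_adjust(p, alpha)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class ActivityResult:
    gene_set_id: str
    auc: np.ndarray
    threshold: float
    bimodal: bool
    p_adj: np.ndarray
    assigned: np.ndarray  # bool per cell
    cell_ids: np.ndarray

    @property
    def assigned_cells(self) -> set:
        return set(self.cell_ids[self.assigned])


def assign_cells(auc: np.ndarray, threshold: float, p_adj: np.ndarray,
                 alpha: float = 0.05) -> np.ndarray:
    """Intersection rule: assigned iff AUC >= threshold and p_adj < alpha."""
    auc = np.asarray(auc, float)
    p_adj = np.asarray(p_adj, float)
    if auc.shape != p_adj.shape:
        raise ValueError("auc and p_adj must align on cells")
    return (auc >= threshold) & (p_adj < alpha)


def score_target_set(rankings: RankingMatrix, gene_set, gene_set_id: str,
                     config, threshold: float | None = None) -> ActivityResult:
    """AUC + threshold + KW significance + assignment for one target set.

    ``threshold`` may be supplied to score one population against a
    threshold learned on another (e.g. a reference tissue's mixture fit).
    """
    auc = auc_score(rankings, gene_set, config.auc_top_fraction)
    if threshold is None:
        tr = explore_threshold(auc, seed=config.rng_seed)
        threshold, bimodal = tr.threshold, tr.bimodal
    else:
        bimodal = True
    _, holm = kw_significance(rankings, gene_set, config.alpha)
    assigned = assign_cells(auc, threshold, holm.p_adj, config.alpha)
    return ActivityResult(gene_set_id=gene_set_id, auc=auc, threshold=float(threshold),
                          bimodal=bimodal, p_adj=holm.p_adj, assigned=assigned,
                          cell_ids=rankings.cell_ids)
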