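"""Composite EHT-potential score and tissue ranking.

Each tissue gets three raw components measured on its endothelial cells:

* frequency score -- mean seed-TF detection fraction;
* co-expression score -- mean per-cell fraction of co-detected sub-panel TFs;
* network score -- 0.5 * (TFs with a positive, endothelially expressed
  target set / panel size) + 0.5 * (overlap-clique size / panel size).

Components are normalized to their maximum across tissues and averaged
into a composite in [0, 1]; tissues are ranked by descending composite
with deterministic, flagged tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SeedPanel
from .grn import GRNResult
from .signatures import OverlapMatrix
from .tfpanel import CoexpressionDistribution

log = logging.getLogger("hemorank")

ENDOTHELIAL = "endothelial"


@dataclass
class TissueScoreCard:
    tissue: str
    freq_score: float
    coexpr_score: float
    grn_score: float
    normalized: tuple[float, float, float] | None = None
    composite: float | None = None
    rank: int | None = None
    tied: bool = False


def frequency_score(freq_profile: pd.DataFrame, tissue: str,
                    panel: SeedPanel) -> float:
    """Mean detection fraction of the seed TFs in the tissue's endothelium;
    a TF missing from the profile counts as 0."""
    sub = freq_profile[(freq_profile.tissue == tissue) &
                       (freq_profile.population == ENDOTHELIAL)]
    by_tf = dict(zip(sub.tf, sub.detect_fraction))
    vals = []
    for tf in panel.seed_tfs:
        if tf not in by_tf:
            log.warning("frequency_score: %s missing for %s, treated as 0", tf, tissue)
        vals.append(by_tf.get(tf, 0.0))
    return float(np.mean(vals))


def coexpression_score(dist: CoexpressionDistribution, tissue: str) -> float:
    """Mean per-cell co-detected fraction of the sub-panel (mean k / K)."""
    return dist.mean_fraction_coexpressed(tissue, ENDOTHELIAL)


def grn_score(grn: GRNResult, ec_assigned_fraction: dict[str, float],
              overlap: OverlapMatrix | None, panel: SeedPanel) -> float:
    """Network component for one tissue.

    ``ec_assigned_fraction`` maps each TF to the fraction of the tissue's
    endothelial cells assigned to its target set by the activity analysis;
    a TF counts toward the score when it has a retained positive edge and
    that fraction is > 0.
    """
    n_panel = len(panel.seed_tfs)
    pos = {tf for tf in grn.positive_tfs()
           if ec_assigned_fraction.get(tf, 0.0) > 0.0}
    clique = len(overlap.clique_tfs) if overlap is not None else 0
    return 0.5 * len(pos) / n_panel + 0.5 * clique / n_panel


def rank_tissues(cards: list[TissueScoreCard]) -> list[TissueScoreCard]:
    """Max-normalize each component across tissues, average into the
    composite, and rank by descending composite.

    Ties are broken deterministically by (freq_score desc, tissue name)
    and flagged.  A component that is zero everywhere contributes 0 for
    all tissues (flagged in the log).
    """
    if len(cards) < 2:
        raise ValueError("need >= 2 tissues to rank")
    comps = np.array([[c.freq_score, c.coexpr_score, c.grn_score] for c in cards])
    if (comps < 0).any():
        raise ValueError("raw component scores must be >= 0")
    maxima = comps.max(axis=0)
    normed = np.zeros_like(comps)
    for j, name in enumerate(("frequency", "co-expression", "network")):
        if maxima[j] > 0:
            normed[:, j] = comps[:, j] / maxima[j]
        else:
            log.warning("rank_tissues: %s component is zero for all tissues", name)
    composite = normed.mean(axis=1)
    for c, nrm, comp in zip(cards, normed, composite):
        c.normalized = tuple(float(v) for v in nrm)
        c.composite = float(comp)
    order = sorted(range(len(cards)),
                   key=lambda i: (-composite[i], -cards[i].freq_score,
                                  cards[i].tissue))
    rounded = np.round(composite, 12)
    for rank, i in enumerate(order, start=1):
        cards[i].rank = rank
        cards[i].tied = int((rounded == rounded[i]).sum()) > 1
        if cards[i].tied:
            log.warning("rank_tissues: composite tie involving %s", cards[i].tissue)
    return sorted(cards, key=lambda c: c.rank)


def scorecard_frame(cards: list[TissueScoreCard]) -> pd.DataFrame:
    rows = []
    for c in cards:
        rows.append({
            "tissue": c.tissue, "rank": c.rank,
            "freq_score": c.freq_score, "coexpr_score": c.coexpr_score,
            "grn_score": c.grn_score,
            "freq_norm": c.normalized[0] if c.normalized else np.nan,
            "coexpr_norm": c.normalized[1] if c.normalized else np.nan,
            "grn_norm": c.normalized[2] if c.normalized else np.nan,
            "composite": c.composite, "tied": c.tied,
        })
    return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
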