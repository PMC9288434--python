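"""End-to-end orchestration: simulate/load -> preprocess -> TF panel ->
GRN -> activity -> overlaps -> Runx1+ signatures -> tissue ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activity as activity_mod
from . import signatures as sig_mod
from .core_io import ExpressionBundle, PipelineConfig, SeedPanel
from .grn import GRNResult, SampleSizeError, infer_network
from .preprocess import preprocess
from .ranking import (TissueScoreCard, coexpression_score, frequency_score,
                      grn_score, rank_tissues, scorecard_frame)
from .synthdata import ENDOTHELIAL, LEUKOCYTE, SyntheticTruth, default_cohort, generate_cohort
from .tfpanel import panel_coexpression, tf_frequency

log = logging.getLogger("hemorank")


@dataclass
class PipelineResults:
    bundle: ExpressionBundle
    freq_profile: pd.DataFrame
    coexpr_subset: "object"            # CoexpressionDistribution over the sub-panel
    coexpr_full: "object"              # ... over the full 11-TF panel
    grn: dict[tuple[str, str], GRNResult]
    overlaps: dict[tuple[str, str], object]
    activity: dict[str, dict[str, object]]          # tissue -> tf -> ActivityResult
    ec_assigned_fraction: dict[str, dict[str, float]]
    marker_lists: dict[str, list[str]]
    recurrence: object | None
    split_failures: dict[str, str]
    scorecards: list[TissueScoreCard] = field(default_factory=list)
    truth: SyntheticTruth | None = None

    def scorecard_frame(self) -> pd.DataFrame:
        return scorecard_frame(self.scorecards)

    def ranked_tissues(self) -> list[str]:
        return [c.tissue for c in self.scorecards]


def _grn_populations(bundle: ExpressionBundle, tissue: str) -> list[str]:
    """Endothelium always; leukocyte populations too (they can carry
    confounding TF modules, which the overlap report must localize)."""
    pops = bundle.cell_meta.loc[bundle.cell_meta.tissue == tissue, "population"]
    out = [ENDOTHELIAL] if ENDOTHELIAL in set(pops) else []
    if LEUKOCYTE in set(pops):
        out.append(LEUKOCYTE)
    return out


def run_all(bundle: ExpressionBundle, config: PipelineConfig, panel: SeedPanel,
            truth: SyntheticTruth | None = None,
            skip_preprocess: bool = False) -> PipelineResults:
    """Run every analysis stage on a bundle and rank its tissues."""
    if not skip_preprocess:
        bundle = preprocess(bundle, config, panel)
    elif bundle.normalized is None:
        raise ValueError("skip_preprocess requires a normalized bundle")

    freq_profile = tf_frequency(bundle, panel)
    coexpr_subset = panel_coexpression(bundle, panel, full_panel=False)
    coexpr_full = panel_coexpression(bundle, panel, full_panel=True)

    tissues = list(dict.fromkeys(bundle.cell_meta["tissue"]))
    grn_results: dict[tuple[str, str], GRNResult] = {}
    overlaps: dict[tuple[str, str], object] = {}
    for tissue in tissues:
        for pop in _grn_populations(bundle, tissue):
            try:
                res = infer_network(bundle, panel, tissue, pop, config)
            except SampleSizeError as e:
                log.warning("GRN skipped: %s", e)
                continue
            grn_results[(tissue, pop)] = res
            tsets = {tf: res.target_sets.get(tf, set()) for tf in panel.seed_tfs}
            overlaps[(tissue, pop)] = sig_mod.pairwise_overlap(tsets)

    # activity: per tissue, rank that tissue's cells once, then score every
    # endothelial-network target set and record per-population assignment
    activity: dict[str, dict[str, object]] = {}
    ec_frac: dict[str, dict[str, float]] = {}
    norm = bundle.normalized_dense()
    for tissue in tissues:
        cells = (bundle.cell_meta["tissue"] == tissue).to_numpy()
        rankings = activity_mod.build_rankings(
            norm[cells], bundle.gene_ids, bundle.cell_ids[cells],
            seed=config.rng_seed)
        is_ec = (bundle.cell_meta.loc[cells, "population"] == ENDOTHELIAL).to_numpy()
        activity[tissue] = {}
        ec_frac[tissue] = {}
        res = grn_results.get((tissue, ENDOTHELIAL))
        if res is None:
            continue
        for tf, targets in res.target_sets.items():
            if len(targets) < 2:  # KW set-vs-background needs >= 2 set genes
                if targets:
                    log.info("activity: %s/%s target set too small, skipped",
                             tissue, tf)
                continue
            act = activity_mod.score_target_set(rankings, sorted(targets), tf, config)
            activity[tissue][tf] = act
            ec_frac[tissue][tf] = float(act.assigned[is_ec].mean()) if is_ec.any() else 0.0

    # Runx1+ signatures
    marker_lists: dict[str, list[str]] = {}
    split_failures: dict[str, str] = {}
    for tissue in tissues:
        try:
            labels = sig_mod.split_by_tf(bundle, tissue, ENDOTHELIAL, tf="Runx1")
            sub = bundle.subset(cell_mask=bundle.cell_meta.index.isin(labels.index))
            markers = sig_mod.marker_genes(sub, labels, config.alpha,
                                           config.marker_lfc_threshold)
            marker_lists[tissue] = markers.loc[markers.is_marker, "gene"].tolist()
        except sig_mod.SplitError as e:
            split_failures[tissue] = str(e)
            log.info("Runx1 split unavailable for %s: %s", tissue, e)
    rec = None
    if len(marker_lists) >= config.recurrence_min_tissues:
        rec = sig_mod.recurrence(marker_lists, config.recurrence_min_tissues)

    # composite ranking
    cards = []
    for tissue in tissues:
        res = grn_results.get((tissue, ENDOTHELIAL))
        ov = overlaps.get((tissue, ENDOTHELIAL))
        g = grn_score(res, ec_frac.get(tissue, {}), ov, panel) if res else 0.0
        cards.append(TissueScoreCard(
            tissue=tissue,
            freq_score=frequency_score(freq_profile, tissue, panel),
            coexpr_score=coexpression_score(coexpr_subset, tissue),
            grn_score=g,
        ))
    cards = rank_tissues(cards)

    return PipelineResults(
        bundle=bundle, freq_profile=freq_profile,
        coexpr_subset=coexpr_subset, coexpr_full=coexpr_full,
        grn=grn_results, overlaps=overlaps, activity=activity,
        ec_assigned_fraction=ec_frac, marker_lists=marker_lists,
        recurrence=rec, split_failures=split_failures,
        scorecards=cards, truth=truth,
    )


def run_default_cohort(seed: int, config: PipelineConfig | None = None,
                       panel: SeedPanel | None = None) -> PipelineResults:
    """Simulate the default six-tissue cohort and analyze it end to end."""
    panel = panel or SeedPanel()
    config = config or PipelineConfig()
    config = type(config)(**{**config.__dict__, "rng_seed": int(seed)})
    bundle, truth = generate_cohort(default_cohort(), seed=int(seed), panel=panel)
    results = run_all(bundle, config, panel, truth=truth)
    return results


def rank_recovery_spearman(results: PipelineResults) -> float:
    """Spearman correlation between recovered and true tissue order."""
    if results.truth is None:
        raise ValueError("results carry no synthetic truth")
    import scipy.stats
    true_order = results.truth.true_tissue_order
    recovered = results.ranked_tissues()
    true_rank = {t: i for i, t in enumerate(true_order)}
    rec_rank = {t: i for i, t in enumerate(recovered)}
    tissues = sorted(true_rank)
    a = [true_rank[t] for t in tissues]
    b = [rec_rank[t] for t in tissues]
    return float(scipy.stats.spearmanr(a, b).statistic)
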