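"""Multi-tissue synthetic single-cell expression with planted ground truth.

The generator emulates the structure of a cross-tissue endothelial
compendium at desk scale: each tissue carries an endothelial population
plus non-endothelial populations, per-TF detection frequencies ranging
from near-100% (embryo-like) to <25% (adult-like), signed TF->target
regulatory modules, indirect TF->mediator->target chains, Bernoulli
dropout and overdispersed (negative binomial) counts.

Model
-----
* Seed-TF expression per cell: on/off ~ Bernoulli(detection frequency);
  "on" counts are 1 + NB(mean, dispersion), so a planted frequency is the
  exact detection probability.
* Regulatory effects act on target NB means through a log link of the
  standardized (z-scored log1p) regulator expression:
  ``mean = baseline * exp(sum sign * effect * z_tf)``.
* Indirect chains route TF -> mediator -> target with no direct term, so
  the partial distance correlation of (tf, target) given the mediator is
  indistinguishable from zero.
* TF couplings let one seed TF's expression level drive another's,
  producing seed-TF-mediated indirect dependencies (the pruning test bed).
* Dropout zeroes non-seed counts with fixed probability; seed-TF
  detection is governed by the planted frequency alone (that frequency is
  the ground truth every downstream score is checked against).

Everything is bit-reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ExpressionBundle, SeedPanel

ENDOTHELIAL = "endothelial"
LEUKOCYTE = "leukocyte"

_SAT_SCALE = 4.0  # log-link exponents saturate (tanh) at this scale


def _saturate(logfac: np.ndarray) -> np.ndarray:
    """Saturating transcriptional response: keeps the log-link monotone but
    caps fold-changes at exp(+-_SAT_SCALE)."""
    return _SAT_SCALE * np.tanh(logfac / _SAT_SCALE)


@dataclass(frozen=True)
class PlantedEdge:
    tf: str
    target: str
    sign: str  # "+" or "-"
    effect: float

    def signed_effect(self) -> float:
        if self.sign not in ("+", "-"):
            raise ValueError(f"edge sign must be '+' or '-', got {self.sign!r}")
        return self.effect if self.sign == "+" else -self.effect


@dataclass(frozen=True)
class IndirectChain:
    tf: str
    mediator: str
    target: str
    effect_tm: float = 1.2
    effect_mt: float = 1.5


@dataclass(frozen=True)
class TFCoupling:
    """Driver seed TF modulates the expression level of a driven seed TF."""
    driver: str
    driven: str
    effect: float = 1.2


@dataclass
class TissueSpec:
    """Generative recipe for one tissue."""

    name: str
    n_cells_by_population: dict[str, int]
    tf_detect_freq: dict[str, float]  # endothelial population
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    indirect_chains: list[IndirectChain] = field(default_factory=list)
    tf_couplings: list[TFCoupling] = field(default_factory=list)
    n_background_genes: int = 150
    nb_dispersion: float = 15.0
    dropout_rate: float = 0.05
    tf_detect_freq_by_population: dict[str, dict[str, float]] = field(default_factory=dict)
    other_population_tf_freq: float = 0.05
    tf_mean: float = 8.0
    baseline_mean: float = 5.0
    n_housekeeping_genes: int = 3
    housekeeping_mean: float = 400.0
    housekeeping_dispersion: float = 50.0

    def validate(self, panel: SeedPanel) -> None:
        seeds = set(panel.seed_tfs)
        for tf, f in self.tf_detect_freq.items():
            if tf not in seeds:
                raise ValueError(f"{self.name}: tf_detect_freq key {tf!r} not in seed panel")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}: frequency out of [0,1] for {tf}")
        for pop, n in self.n_cells_by_population.items():
            if n <= 0:
                raise ValueError(f"{self.name}: population {pop!r} size must be > 0")
        for e in self.planted_edges:
            if e.tf not in seeds:
                raise ValueError(f"{self.name}: edge tf {e.tf!r} not in seed panel")
            if e.target in seeds:
                raise ValueError(f"{self.name}: edge target {e.target!r} is a seed TF")
            e.signed_effect()
        chain_targets = set()
        for c in self.indirect_chains:
            if c.tf not in seeds:
                raise ValueError(f"{self.name}: chain tf {c.tf!r} not in seed panel")
            if c.mediator in seeds or c.target in seeds:
                raise ValueError(f"{self.name}: chain mediator/target must be non-seed genes")
            chain_targets.update((c.mediator, c.target))
        planted_targets = {e.target for e in self.planted_edges}
        overlap = chain_targets & planted_targets
        if overlap:
            raise ValueError(f"{self.name}: genes both chained and directly planted: {sorted(overlap)}")
        for c in self.tf_couplings:
            if c.driver not in seeds or c.driven not in seeds:
                raise ValueError(f"{self.name}: tf_couplings must link seed TFs")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")

    def population_freq(self, population: str, tf: str) -> float:
        if population in self.tf_detect_freq_by_population:
            pop_map = self.tf_detect_freq_by_population[population]
            if tf in pop_map:
                return pop_map[tf]
            return self.other_population_tf_freq
        if population == ENDOTHELIAL:
            return self.tf_detect_freq.get(tf, 0.0)
        return self.other_population_tf_freq

    def module_genes(self) -> list[str]:
        """Non-seed genes this tissue actively models (targets + mediators)."""
        out: list[str] = []
        for e in self.planted_edges:
            if e.target not in out:
                out.append(e.target)
        for c in self.indirect_chains:
            for g in (c.mediator, c.target):
                if g not in out:
                    out.append(g)
        return out


@dataclass
class SyntheticTruth:
    """Machine-readable oracle serialized next to a generated bundle."""

    specs: list[TissueSpec]
    true_tissue_order: list[str]
    tf_states: pd.DataFrame  # cells x seed TFs, boolean on/off

    def positive_edges(self, tissue: str) -> set[tuple[str, str]]:
        spec = {s.name: s for s in self.specs}[tissue]
        return {(e.tf, e.target) for e in spec.planted_edges if e.sign == "+"}

    def to_json(self) -> str:
        payload = {
            "true_tissue_order": self.true_tissue_order,
            "specs": [asdict(s) for s in self.specs],
            "tf_states": {
                "columns": list(self.tf_states.columns),
                "cells": list(self.tf_states.index),
                "bits": ["".join("1" if b else "0" for b in row)
                         for row in self.tf_states.to_numpy()],
            },
        }
        return json.dumps(payload, indent=0)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        specs = []
        for raw in payload["specs"]:
            raw = dict(raw)
            raw["planted_edges"] = [PlantedEdge(**e) for e in raw["planted_edges"]]
            raw["indirect_chains"] = [IndirectChain(**c) for c in raw["indirect_chains"]]
            raw["tf_couplings"] = [TFCoupling(**c) for c in raw["tf_couplings"]]
            specs.append(TissueSpec(**raw))
        ts = payload["tf_states"]
        mat = np.array([[ch == "1" for ch in bits] for bits in ts["bits"]], dtype=bool)
        states = pd.DataFrame(mat, index=ts["cells"], columns=ts["columns"])
        return cls(specs=specs, true_tissue_order=payload["true_tissue_order"],
                   tf_states=states)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Gene space
# ---------------------------------------------------------------------------

def background_gene_means(n: int) -> np.ndarray:
    """Deterministic abundance ladder for background genes.

    The first (up to) 10 genes are dense housekeeping-like noise (NB mean
    1.5-3), the rest are rare transcripts with detection well below 10% so
    they never enter the GRN candidate family.
    """
    if n <= 0:
        return np.zeros(0)
    n_dense = min(5, n)
    dense = np.linspace(1.5, 3.0, n_dense)
    n_rare = n - n_dense
    rare = np.geomspace(0.005, 0.05, n_rare) if n_rare else np.zeros(0)
    return np.concatenate([dense, rare])


def background_gene_names(n: int) -> list[str]:
    return [f"Bg{i + 1:03d}" for i in range(n)]


def housekeeping_gene_names(n: int) -> list[str]:
    return [f"Hk{i + 1}" for i in range(n)]


def _tissue_gene_list(spec: TissueSpec, panel: SeedPanel) -> list[str]:
    return list(panel.seed_tfs) + spec.module_genes() + \
        housekeeping_gene_names(spec.n_housekeeping_genes) + \
        background_gene_names(spec.n_background_genes)


def _standardize(values: np.ndarray) -> np.ndarray:
    z = np.log1p(values.astype(float))
    sd = z.std()
    if sd < 1e-12:
        return np.zeros_like(z)
    return (z - z.mean()) / sd


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size/dispersion ``r``."""
    mean = np.asarray(mean, dtype=float)
    if size is None:
        size = mean.shape
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_tissue(spec: TissueSpec, seed: int, panel: SeedPanel | None = None,
                    gene_ids: list[str] | None = None,
                    bg_means: dict[str, float] | None = None):
    """Generate one tissue's counts plus per-cell TF truth.

    Returns ``(counts int array cells x genes, cell_meta DataFrame,
    tf_states boolean DataFrame)``.  ``gene_ids`` may supply a cohort-wide
    gene list (a superset); genes not modeled by this tissue fall back to
    baseline (former module pool) or background behavior.
    """
    panel = panel or SeedPanel()
    spec.validate(panel)
    rng = np.random.default_rng(seed)

    if gene_ids is None:
        gene_ids = _tissue_gene_list(spec, panel)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for g in spec.module_genes():
        if g not in gene_pos:
            raise ValueError(f"gene list lacks module gene {g!r}")

    bg_names = [g for g in gene_ids if g.startswith("Bg")]
    if bg_means is None:
        means = background_gene_means(len(bg_names))
        bg_means = dict(zip(bg_names, means))

    populations: list[str] = []
    for pop, n in spec.n_cells_by_population.items():
        populations.extend([pop] * n)
    n_cells = len(populations)
    pop_arr = np.array(populations)

    seeds = list(panel.seed_tfs)
    n_tf = len(seeds)
    freq = np.empty((n_cells, n_tf))
    for j, tf in enumerate(seeds):
        for pop in spec.n_cells_by_population:
            freq[pop_arr == pop, j] = spec.population_freq(pop, tf)

    on = rng.random((n_cells, n_tf)) < freq

    # seed-TF expression; coupled TFs are filled after their drivers
    driven = {c.driven: c for c in spec.tf_couplings}
    if set(driven) & {c.driver for c in spec.tf_couplings}:
        raise ValueError("tf_couplings must not chain (driven TF cannot also drive)")
    tf_counts = np.zeros((n_cells, n_tf), dtype=np.int64)
    on_mean = max(spec.tf_mean - 1.0, 0.5)
    for j, tf in enumerate(seeds):
        if tf in driven:
            continue
        tf_counts[:, j] = on[:, j] * (1 + _nb_draw(rng, np.full(n_cells, on_mean),
                                                   spec.nb_dispersion))
    z_tf = {tf: _standardize(tf_counts[:, j]) for j, tf in enumerate(seeds)
            if tf not in driven}
    for j, tf in enumerate(seeds):
        if tf not in driven:
            continue
        c = driven[tf]
        logfac = c.effect * z_tf[c.driver]
        if not np.isfinite(logfac).all():
            raise ValueError(f"{spec.name}: coupling effect for {tf} produces non-finite means")
        mean = on_mean * np.exp(_saturate(logfac))
        tf_counts[:, j] = on[:, j] * (1 + _nb_draw(rng, mean, spec.nb_dispersion))
        z_tf[tf] = _standardize(tf_counts[:, j])

    counts = np.zeros((n_cells, len(gene_ids)), dtype=np.int64)
    for j, tf in enumerate(seeds):
        counts[:, gene_pos[tf]] = tf_counts[:, j]

    # planted direct targets
    edges_by_target: dict[str, list[PlantedEdge]] = {}
    for e in spec.planted_edges:
        edges_by_target.setdefault(e.target, []).append(e)
    for target, edges in edges_by_target.items():
        logfac = np.zeros(n_cells)
        for e in edges:
            logfac += e.signed_effect() * z_tf[e.tf]
        if not np.isfinite(logfac).all():
            raise ValueError(f"{spec.name}: effects on {target!r} produce non-finite means")
        mean = spec.baseline_mean * np.exp(_saturate(logfac))
        counts[:, gene_pos[target]] = _nb_draw(rng, mean, spec.nb_dispersion)

    # indirect chains: tf -> mediator -> target, no direct tf term
    for c in spec.indirect_chains:
        med_mean = spec.baseline_mean * np.exp(_saturate(c.effect_tm * z_tf[c.tf]))
        med = _nb_draw(rng, med_mean, spec.nb_dispersion)
        counts[:, gene_pos[c.mediator]] = med
        z_med = _standardize(med)
        tgt_mean = spec.baseline_mean * np.exp(_saturate(c.effect_mt * z_med))
        counts[:, gene_pos[c.target]] = _nb_draw(rng, tgt_mean, spec.nb_dispersion)

    # housekeeping genes: stable, high-mass transcriptome surrogate that
    # anchors per-cell totals (in real data the library is dominated by
    # genes outside the analysis panel)
    hk_names = [g for g in gene_ids if g.startswith("Hk")]
    for g in hk_names:
        counts[:, gene_pos[g]] = _nb_draw(
            rng, np.full(n_cells, spec.housekeeping_mean),
            spec.housekeeping_dispersion)

    # remaining non-seed genes: cohort module genes unmodeled here sit at
    # baseline; background genes follow the abundance ladder
    modeled = set(seeds) | set(edges_by_target) | set(hk_names) | \
        {g for c in spec.indirect_chains for g in (c.mediator, c.target)}
    for g in gene_ids:
        if g in modeled:
            continue
        if g in bg_means:
            mean = np.full(n_cells, bg_means[g])
        else:
            mean = np.full(n_cells, spec.baseline_mean)
        counts[:, gene_pos[g]] = _nb_draw(rng, mean, spec.nb_dispersion)

    # dropout on non-seed genes only: seed-TF detection frequency is the
    # planted truth and already folds capture efficiency in
    if spec.dropout_rate > 0:
        non_seed = np.array([g not in set(seeds) for g in gene_ids])
        drop = rng.random((n_cells, int(non_seed.sum()))) < spec.dropout_rate
        block = counts[:, non_seed]
        block[drop] = 0
        counts[:, non_seed] = block

    cell_ids = [f"{spec.name}.{pop_arr[i]}.{i:05d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {"tissue": spec.name, "population": pop_arr, "dataset": "synthetic"},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    tf_states = pd.DataFrame(on, index=meta.index, columns=seeds)
    return counts, meta, tf_states


def _ordering_key(spec: TissueSpec) -> float:
    """Construction-defined EHT-potential proxy: mean endothelial seed-TF
    frequency times (1 + number of endothelially active planted edges)."""
    freqs = [spec.tf_detect_freq.get(tf, 0.0) for tf in spec.tf_detect_freq] or [0.0]
    mean_freq = float(np.mean(list(spec.tf_detect_freq.values()))) if spec.tf_detect_freq else 0.0
    ec_edges = sum(1 for e in spec.planted_edges
                   if spec.tf_detect_freq.get(e.tf, 0.0) > 0)
    return mean_freq * (1 + ec_edges)


def generate_cohort(specs: list[TissueSpec], seed: int,
                    panel: SeedPanel | None = None):
    """Concatenate tissues into one bundle; returns (bundle, truth)."""
    panel = panel or SeedPanel()
    if len(specs) < 2:
        raise ValueError("cohort needs at least 2 tissues")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tissue names")
    for s in specs:
        s.validate(panel)

    module_genes: list[str] = []
    for s in specs:
        for g in s.module_genes():
            if g not in module_genes:
                module_genes.append(g)
    n_bg = max(s.n_background_genes for s in specs)
    n_hk = max(s.n_housekeeping_genes for s in specs)
    bg_names = background_gene_names(n_bg)
    gene_ids = (list(panel.seed_tfs) + module_genes +
                housekeeping_gene_names(n_hk) + bg_names)
    bg_means = dict(zip(bg_names, background_gene_means(n_bg)))

    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2 ** 31)
    blocks, metas, states = [], [], []
    for s, cs in zip(specs, child_seeds):
        c, m, st = generate_tissue(s, int(cs), panel, gene_ids, bg_means)
        blocks.append(c)
        metas.append(m)
        states.append(st)
    counts = np.vstack(blocks)
    meta = pd.concat(metas)
    tf_states = pd.concat(states)

    order = sorted(names, key=lambda n: -_ordering_key({s.name: s for s in specs}[n]))
    bundle = ExpressionBundle(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=meta.index.to_numpy(dtype=object),
        cell_meta=meta,
    )
    truth = SyntheticTruth(specs=specs, true_tissue_order=order, tf_states=tf_states)
    return bundle, truth


# ---------------------------------------------------------------------------
# The default six-tissue cohort
# ---------------------------------------------------------------------------

COMMON_TARGETS = ["Tcom1", "Tcom2", "Tcom3", "Tcom4"]
LEUKO_TARGETS = ["Tleu1", "Tleu2", "Tleu3"]

#: effect sizes (log-link units) for module edges; shared-module edges are
#: weaker per regulator because eight regulators sum on the same target
SHARED_EFFECT = 0.7
PRIVATE_EFFECT = 1.2
NEGATIVE_EFFECT = 1.0
LEUKO_EFFECT = 1.2

MODERATE_TFS = ("Cbfa2t3", "Cbfb", "Erg", "Fli1", "Gata2", "Ldb1", "Lmo2")
LOW_TFS = ("Tal1", "Lyl1", "Runx1")


def private_targets(tf: str) -> list[str]:
    return [f"Tp{tf}1", f"Tp{tf}2"]


def _module_edges(tfs: list[str], n_common: int, with_private: int) -> list[PlantedEdge]:
    """Clique module: each TF hits the first ``n_common`` shared targets plus
    its first ``with_private`` private targets."""
    edges = []
    for tf in tfs:
        for t in COMMON_TARGETS[:n_common]:
            edges.append(PlantedEdge(tf, t, "+", SHARED_EFFECT))
        for t in private_targets(tf)[:with_private]:
            edges.append(PlantedEdge(tf, t, "+", PRIVATE_EFFECT))
    return edges


def _runx1_program() -> list[PlantedEdge]:
    return [PlantedEdge("Runx1", t, "+", PRIVATE_EFFECT) for t in private_targets("Runx1")]


def _freqs(moderate: float, low: float, gata1: float, runx1: float | None = None) -> dict:
    f = {tf: moderate for tf in MODERATE_TFS}
    for tf in LOW_TFS:
        f[tf] = low
    f["Gata1"] = gata1
    if runx1 is not None:
        f["Runx1"] = runx1
    return f


def default_cohort() -> list[TissueSpec]:
    """Six tissues in decreasing EHT potential.

    * ``embryo``: embryo-like; every seed-TF frequency 0.95, full module
      set (8-TF shared-target clique + private targets, Runx1 included,
      one repressive Gata1 edge).
    * ``brain`` > ``kidney`` > ``liver``: graded adult-like tissues with
      shrinking frequencies and clique modules; each keeps a small Runx1
      program so Runx1+ signatures recur across >= 4 tissues.
    * ``pancreas``: adult-like with *no* endothelial Runx1 expression but a
      leukocyte population carrying a strong Fli1/Runx1 shared module --
      the white-blood-cell confound.
    * ``null``: no planted edges, all frequencies 0.05.
    """
    coexpr = list(SeedPanel().coexpr_subset)  # the 8-TF clique panel
    extra = [tf for tf in SeedPanel().seed_tfs if tf not in coexpr]

    embryo_edges = _module_edges(coexpr, n_common=4, with_private=2)
    for tf in extra:  # Cbfa2t3, Gata1, Ldb1: private-only modules
        embryo_edges += [PlantedEdge(tf, t, "+", PRIVATE_EFFECT)
                         for t in private_targets(tf)]
    # one repressive edge so negative sign assignment is exercised
    embryo_edges = [e if not (e.tf == "Gata1" and e.target == "TpGata12")
                    else PlantedEdge("Gata1", "TpGata12", "-", NEGATIVE_EFFECT)
                    for e in embryo_edges]

    brain_edges = _module_edges(["Erg", "Fli1", "Lmo2", "Cbfb", "Gata2", "Ldb1"],
                                n_common=3, with_private=1) + _runx1_program()
    kidney_edges = _module_edges(["Erg", "Fli1", "Lmo2", "Gata2"],
                                 n_common=2, with_private=1) + _runx1_program()
    liver_edges = _module_edges(["Erg", "Fli1", "Cbfb"],
                                n_common=2, with_private=1) + _runx1_program()
    pancreas_edges = _module_edges(["Erg", "Fli1"], n_common=2, with_private=1)
    for tf in ("Fli1", "Runx1"):
        pancreas_edges += [PlantedEdge(tf, t, "+", LEUKO_EFFECT) for t in LEUKO_TARGETS]

    specs = [
        TissueSpec(
            name="embryo",
            n_cells_by_population={ENDOTHELIAL: 500, "other": 120},
            tf_detect_freq={tf: 0.90 for tf in SeedPanel().seed_tfs},
            planted_edges=embryo_edges,
        ),
        TissueSpec(
            name="brain",
            n_cells_by_population={ENDOTHELIAL: 250, "other": 100},
            tf_detect_freq=_freqs(0.60, 0.22, 0.12, runx1=0.20),
            planted_edges=brain_edges,
        ),
        TissueSpec(
            name="kidney",
            n_cells_by_population={ENDOTHELIAL: 250, "other": 100},
            tf_detect_freq=_freqs(0.45, 0.15, 0.08),
            planted_edges=kidney_edges,
        ),
        TissueSpec(
            name="liver",
            n_cells_by_population={ENDOTHELIAL: 250, "other": 100},
            tf_detect_freq=_freqs(0.35, 0.12, 0.06),
            planted_edges=liver_edges,
        ),
        TissueSpec(
            name="pancreas",
            n_cells_by_population={ENDOTHELIAL: 250, "other": 100, LEUKOCYTE: 150},
            tf_detect_freq=_freqs(0.28, 0.10, 0.05, runx1=0.0),
            planted_edges=pancreas_edges,
            tf_detect_freq_by_population={
                LEUKOCYTE: {"Fli1": 0.9, "Runx1": 0.9},
            },
        ),
        TissueSpec(
            name="null",
            n_cells_by_population={ENDOTHELIAL: 250, "other": 100},
            tf_detect_freq={tf: 0.05 for tf in SeedPanel().seed_tfs},
            planted_edges=[],
        ),
    ]
    return specs


def indirect_chain_spec(n_cells: int = 1000, tf: str = "Fli1",
                        tf_freq: float = 0.6) -> TissueSpec:
    """Single-population tissue with one non-seed-mediated chain, for
    conditional-independence property checks."""
    return TissueSpec(
        name="chainsim",
        n_cells_by_population={ENDOTHELIAL: n_cells},
        tf_detect_freq={tf: tf_freq},
        indirect_chains=[IndirectChain(tf, "Tmed", "Tchain")],
        n_background_genes=40,
        dropout_rate=0.0,
    )


def seed_mediator_chain_spec(n_cells: int = 300) -> TissueSpec:
    """Chain with a *seed-TF* mediator: Fli1 drives Gata2's expression level
    and only Gata2 regulates the target, so the inferred Fli1->target edge
    is indirect and should be pruned by conditioning on Gata2."""
    return TissueSpec(
        name="seedchain",
        n_cells_by_population={ENDOTHELIAL: n_cells},
        tf_detect_freq={"Fli1": 0.5, "Gata2": 1.0},
        planted_edges=[PlantedEdge("Gata2", "Tchain", "+", 1.5)],
        tf_couplings=[TFCoupling(driver="Fli1", driven="Gata2", effect=1.2)],
        n_background_genes=40,
        dropout_rate=0.0,
    )
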