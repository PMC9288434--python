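"""Domain types and on-disk formats.

The pipeline's unit of data is the :class:`ExpressionBundle`: a sparse
cells x genes count matrix with per-cell annotations (tissue, population,
dataset) and, after normalization, a matching log-normalized layer.
Bundles are serialized as Matrix Market files plus TSV sidecars so they
stay plain-text and diffable.

Configuration is split between :class:`PipelineConfig` (thresholds,
permutation counts, seeds) and :class:`SeedPanel` (the panel of
hematopoietic seed transcription factors whose expression, co-expression
and regulatory targets drive every downstream analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

log = logging.getLogger("hemorank")

#: The 11 seed transcription factors central to the endothelial-to-hematopoietic
#: transition (EHT): heptad factors plus Runx1/Cbfb and Gata1.
DEFAULT_SEED_TFS: tuple[str, ...] = (
    "Cbfa2t3", "Cbfb", "Erg", "Fli1", "Gata1", "Gata2",
    "Ldb1", "Lmo2", "Lyl1", "Runx1", "Tal1",
)

#: Sub-panel whose simultaneous single-cell co-expression marks endothelium
#: initiating the hematopoietic program.
DEFAULT_COEXPR_SUBSET: tuple[str, ...] = (
    "Cbfb", "Erg", "Fli1", "Gata2", "Lmo2", "Lyl1", "Runx1", "Tal1",
)

MANIFEST_NAME = "manifest.txt"
CELL_META_COLUMNS = ("tissue", "population", "dataset")


class BundleValidationError(ValueError):
    """An ExpressionBundle violates one of its invariants."""


class ConfigError(ValueError):
    """A configuration file contains unknown keys or out-of-range values."""


@dataclass(frozen=True)
class SeedPanel:
    """Ordered seed-TF panel plus the co-expression sub-panel.

    ``moderate_freq_threshold`` separates "moderate" from "low" detection
    frequency (fraction of cells with nonzero counts) when classifying
    per-tissue TF expression.
    """

    seed_tfs: tuple[str, ...] = DEFAULT_SEED_TFS
    coexpr_subset: tuple[str, ...] = DEFAULT_COEXPR_SUBSET
    moderate_freq_threshold: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "seed_tfs", tuple(self.seed_tfs))
        object.__setattr__(self, "coexpr_subset", tuple(self.coexpr_subset))
        if len(set(self.seed_tfs)) != len(self.seed_tfs):
            raise ConfigError("seed_tfs contains duplicates")
        if len(set(self.coexpr_subset)) != len(self.coexpr_subset):
            raise ConfigError("coexpr_subset contains duplicates")
        missing = set(self.coexpr_subset) - set(self.seed_tfs)
        if missing:
            raise ConfigError(f"coexpr_subset genes not in seed_tfs: {sorted(missing)}")
        if not 0.0 < self.moderate_freq_threshold < 1.0:
            raise ConfigError("moderate_freq_threshold must be in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric knobs shared across pipeline stages.

    Attributes
    ----------
    filter_min_cells_per_gene
        A gene is kept only if detected in strictly more than this many cells.
    filter_min_genes_per_cell
        A cell is kept only if it detects at least this many genes.
    lognorm_scale
        Per-cell scale factor of the log-normalization (counts are divided by
        the cell total, multiplied by this, then log1p-transformed).
    alpha
        Family-wise significance level used throughout.
    n_permutations
        Permutations for the stage-1 distance-correlation test.
    n_permutations_conditional
        Permutations for the stage-2 partial-distance-correlation pruning
        test; its decision is only p vs alpha, so a coarser resolution
        suffices.
    auc_top_fraction
        Fraction of the per-cell ranking scanned by the recovery curve.
    pruning_drop_fraction
        An edge is pruned when conditioning on a co-seed drops its
        dependence below this fraction of the unconditional value.
    recurrence_min_tissues
        Minimum number of tissues a marker must recur in to be reported.
    candidate_min_detect_frac
        Candidate GRN targets must be detected in at least this fraction of
        the analyzed population's cells.
    marker_lfc_threshold
        Minimum log fold-change (natural log, normalized units) for markers.
    """

    filter_min_cells_per_gene: int = 10
    filter_min_genes_per_cell: int = 0
    lognorm_scale: float = 10_000.0
    alpha: float = 0.05
    n_permutations: int = 999
    n_permutations_conditional: int = 199
    auc_top_fraction: float = 0.05
    pruning_drop_fraction: float = 0.5
    recurrence_min_tissues: int = 4
    candidate_min_detect_frac: float = 0.10
    marker_lfc_threshold: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "auc_top_fraction", "pruning_drop_fraction",
                     "candidate_min_detect_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v!r}")
        for name in ("filter_min_cells_per_gene", "filter_min_genes_per_cell",
                     "recurrence_min_tissues"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.lognorm_scale <= 0:
            raise ConfigError("lognorm_scale must be positive")
        if self.n_permutations < 99:
            raise ConfigError("n_permutations must be >= 99")
        if self.n_permutations_conditional < 19:
            raise ConfigError("n_permutations_conditional must be >= 19")
        if self.marker_lfc_threshold < 0:
            raise ConfigError("marker_lfc_threshold must be >= 0")


@dataclass
class ExpressionBundle:
    """Sparse cells x genes counts with annotations and an optional
    normalized layer of identical shape."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    normalized: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.normalized is not None:
            self.normalized = sp.csr_matrix(self.normalized)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise BundleValidationError(
                f"gene_ids length {len(self.gene_ids)} != n_genes {n_genes}")
        if len(self.cell_ids) != n_cells:
            raise BundleValidationError(
                f"cell_ids length {len(self.cell_ids)} != n_cells {n_cells}")
        if len(set(self.gene_ids)) != n_genes:
            raise BundleValidationError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n_cells:
            raise BundleValidationError("duplicate cell_ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise BundleValidationError("negative counts")
        if list(self.cell_meta.index) != list(self.cell_ids):
            raise BundleValidationError("cell_meta must be indexed by cell_ids, in order")
        missing = set(CELL_META_COLUMNS) - set(self.cell_meta.columns)
        if missing:
            raise BundleValidationError(f"cell_meta missing columns: {sorted(missing)}")
        if self.normalized is not None:
            if self.normalized.shape != self.counts.shape:
                raise BundleValidationError("normalized layer shape mismatch")
            if self.normalized.nnz and self.normalized.data.min() < 0:
                raise BundleValidationError("negative normalized values")

    # -- conveniences -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Positions of ``genes`` in gene_ids; raises KeyError for absences."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene not in bundle: {e.args[0]!r}") from None

    def subset(self, cell_mask=None, gene_mask=None) -> "ExpressionBundle":
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        counts = self.counts[cm][:, gm]
        norm = self.normalized[cm][:, gm] if self.normalized is not None else None
        return ExpressionBundle(
            counts=counts,
            gene_ids=self.gene_ids[gm],
            cell_ids=self.cell_ids[cm],
            cell_meta=self.cell_meta.loc[cm].copy(),
            normalized=norm,
        )

    def counts_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def normalized_dense(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("normalized layer absent; run lognormalize first")
        return np.asarray(self.normalized.todense())


def bundles_equal(a: ExpressionBundle, b: ExpressionBundle) -> bool:
    """Exact equality of counts, ids, metadata and normalized layer."""
    if (a.counts != b.counts).nnz:
        return False
    if list(a.gene_ids) != list(b.gene_ids) or list(a.cell_ids) != list(b.cell_ids):
        return False
    if not a.cell_meta[list(CELL_META_COLUMNS)].equals(
            b.cell_meta[list(CELL_META_COLUMNS)]):
        return False
    if (a.normalized is None) != (b.normalized is None):
        return False
    if a.normalized is not None and (a.normalized != b.normalized).nnz:
        return False
    return True


# ---------------------------------------------------------------------------
# On-disk format: matrix.mtx (+ normalized.mtx), genes.tsv, cells.tsv,
# manifest.txt declaring orientation.  MTX is 1-based on disk per the Matrix
# Market standard; all in-memory indices are 0-based.
# ---------------------------------------------------------------------------

def write_bundle(bundle: ExpressionBundle, directory) -> None:
    """Write a bundle so that :func:`read_bundle` inverts it exactly."""
    if bundle.n_cells == 0 or bundle.n_genes == 0:
        raise BundleValidationError("refusing to write a degenerate bundle (0 cells or genes)")
    bundle.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), bundle.counts.astype(np.int64),
                     field="integer")
    if bundle.normalized is not None:
        # precision=17 round-trips float64 exactly
        scipy.io.mmwrite(str(d / "normalized.mtx"), bundle.normalized, precision=17)
    pd.DataFrame({"gene_id": bundle.gene_ids}).to_csv(
        d / "genes.tsv", sep="\t", index=False)
    meta = bundle.cell_meta[list(CELL_META_COLUMNS)].copy()
    meta.insert(0, "cell_id", bundle.cell_ids)
    meta.to_csv(d / "cells.tsv", sep="\t", index=False)
    (d / MANIFEST_NAME).write_text("orientation=cells_x_genes\n")


def read_bundle(directory) -> ExpressionBundle:
    """Read a bundle written by :func:`write_bundle` (or compatible)."""
    d = Path(directory)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing bundle file: {d / name}")
    orientation = "cells_x_genes"
    if (d / MANIFEST_NAME).exists():
        text = (d / MANIFEST_NAME).read_text().strip()
        if "=" in text:
            orientation = text.split("=", 1)[1].strip()
    counts = sp.csr_matrix(scipy.io.mmread(str(d / "matrix.mtx")))
    if orientation == "genes_x_cells":
        counts = sp.csr_matrix(counts.T)
    elif orientation != "cells_x_genes":
        raise BundleValidationError(f"unknown orientation {orientation!r}")
    genes = pd.read_csv(d / "genes.tsv", sep="\t")["gene_id"].astype(str).to_numpy()
    cells = pd.read_csv(d / "cells.tsv", sep="\t", dtype=str)
    for col in ("cell_id", *CELL_META_COLUMNS):
        if col not in cells.columns:
            raise BundleValidationError(f"cells.tsv missing column {col!r}")
    normalized = None
    if (d / "normalized.mtx").exists():
        normalized = sp.csr_matrix(scipy.io.mmread(str(d / "normalized.mtx")))
        if orientation == "genes_x_cells":
            normalized = sp.csr_matrix(normalized.T)
    meta = cells.set_index("cell_id")[list(CELL_META_COLUMNS)]
    if counts.nnz and counts.data.min() < 0:
        raise BundleValidationError("negative counts on disk")
    counts = counts.astype(np.int64)
    return ExpressionBundle(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells["cell_id"].to_numpy(),
        cell_meta=meta,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# Config files: YAML with two sections, `pipeline:` and `panel:`.  Unknown
# keys are errors -- no silent typo tolerance.
# ---------------------------------------------------------------------------

def load_config(path=None) -> tuple[PipelineConfig, SeedPanel]:
    """Load config + seed panel from YAML; absent keys take defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    unknown_sections = set(raw) - {"pipeline", "panel"}
    if unknown_sections:
        raise ConfigError(f"unknown config sections: {sorted(unknown_sections)}")

    pipe_raw = dict(raw.get("pipeline") or {})
    known_pipe = {f.name for f in fields(PipelineConfig)}
    unknown = set(pipe_raw) - known_pipe
    if unknown:
        raise ConfigError(f"unknown pipeline keys: {sorted(unknown)}")
    config = PipelineConfig(**pipe_raw)

    panel_raw = dict(raw.get("panel") or {})
    known_panel = {f.name for f in fields(SeedPanel)}
    unknown = set(panel_raw) - known_panel
    if unknown:
        raise ConfigError(f"unknown panel keys: {sorted(unknown)}")
    panel = SeedPanel(**panel_raw)

    log.info("effective pipeline config: %s", config)
    log.info("effective seed panel: %s", panel)
    return config, panel


def with_seed(config: PipelineConfig, seed: int) -> PipelineConfig:
    """Copy of ``config`` with its RNG seed replaced."""
    return replace(config, rng_seed=int(seed))
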