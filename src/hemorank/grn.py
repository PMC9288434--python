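"""Seed-TF -> target network inference with distance correlation.

The statistic is the Szekely--Rizzo sample distance correlation: pairwise
Euclidean distance matrices are double-centered and dCor =
dCov / sqrt(dVar_x dVar_y), which is 0 iff independence in the population
version and detects non-linear, non-monotone dependence.  Significance
comes from a permutation test; indirect relationships are pruned with the
projection-based (U-centered) partial distance correlation, conditioning
only on co-seed TFs that share the target.

Inference proceeds in three stages:

1. For every (seed TF, candidate target) pair, dCor plus a permutation
   p-value; p-values are Holm-adjusted per TF family and edges with
   adjusted p < alpha are kept.
2. For each kept edge (a, t) and every other seed TF b with a kept edge to
   t, the partial distance correlation pdcor(a, t; b) is computed; if
   conditioning removes more than ``pruning_drop_fraction`` of the
   dependence, or kills its significance, the edge is marked pruned_by=b
   and a TF-TF interaction {a, b, t} recorded.
3. Surviving edges get a sign from the Spearman correlation restricted to
   cells where the TF is detected.

Permutation statistics are evaluated through a batched gather + matrix
product: double- and U-centering commute with simultaneous row/column
permutation, so for a fixed TF the permuted centered matrix is gathered
once per permutation and its inner products with all candidate matrices
come from one GEMM.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .activity import holm_adjust
from .core_io import ExpressionBundle, PipelineConfig, SeedPanel

log = logging.getLogger("hemorank")

_DEGENERATE_TOL = 1e-14


class SampleSizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Distance-correlation primitives
# ---------------------------------------------------------------------------

def _dist(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return np.abs(x[:, None] - x[None, :])


def double_center(d: np.ndarray) -> np.ndarray:
    """V-statistic (D-)centering: subtract row/col means, add grand mean."""
    rm = d.mean(axis=1, keepdims=True)
    cm = d.mean(axis=0, keepdims=True)
    return d - rm - cm + d.mean()


def u_center(d: np.ndarray) -> np.ndarray:
    """Bias-corrected U-centering (zero diagonal)."""
    n = d.shape[0]
    if n < 4:
        raise ValueError("U-centering requires n >= 4")
    rs = d.sum(axis=1, keepdims=True)
    cs = d.sum(axis=0, keepdims=True)
    total = d.sum()
    out = d - rs / (n - 2) - cs / (n - 2) + total / ((n - 1) * (n - 2))
    np.fill_diagonal(out, 0.0)
    return out


def _u_inner(a: np.ndarray, b: np.ndarray) -> float:
    n = a.shape[0]
    return float((a * b).sum() / (n * (n - 3)))


def distance_correlation(x, y, return_degenerate: bool = False):
    """Sample distance correlation in [0, 1].

    Constant input (zero distance variance) is degenerate; the result is
    defined as 0 and, when requested, flagged.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("n >= 4 required")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    a = double_center(_dist(x))
    b = double_center(_dist(y))
    dvx = (a * a).mean()
    dvy = (b * b).mean()
    if dvx < _DEGENERATE_TOL or dvy < _DEGENERATE_TOL:
        log.debug("distance_correlation: degenerate (constant) input")
        return (0.0, True) if return_degenerate else 0.0
    dcov2 = (a * b).mean()
    val = float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))
    val = min(val, 1.0)
    return (val, False) if return_degenerate else val


def u_distance_correlation(x, y) -> float:
    """Bias-corrected (U-centered) squared-dCor analogue R*(x, y); can be
    slightly negative under independence."""
    a = u_center(_dist(x))
    b = u_center(_dist(y))
    denom = _u_inner(a, a) * _u_inner(b, b)
    if denom <= _DEGENERATE_TOL:
        return 0.0
    return _u_inner(a, b) / np.sqrt(denom)


def partial_distance_correlation(x, y, z) -> float:
    """Projection-based sample partial distance correlation of x and y
    removing z (U-centered).  Degenerate z falls back to plain dCor."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    z = np.asarray(z, float).ravel()
    if not (len(x) == len(y) == len(z)):
        raise ValueError("equal lengths required")
    az = u_center(_dist(z))
    if _u_inner(az, az) <= _DEGENERATE_TOL:
        log.warning("partial_distance_correlation: degenerate z, "
                    "falling back to plain dCor")
        return distance_correlation(x, y)
    ax = u_center(_dist(x))
    ay = u_center(_dist(y))
    return _pdcor_from_inners(
        _u_inner(ax, ay), _u_inner(ax, az), _u_inner(ay, az),
        _u_inner(ax, ax), _u_inner(ay, ay), _u_inner(az, az))


def _pdcor_from_inners(sxy, sxz, syz, sxx, syy, szz) -> float:
    def r(sab, saa, sbb):
        d = saa * sbb
        return sab / np.sqrt(d) if d > _DEGENERATE_TOL else 0.0
    rxy, rxz, ryz = r(sxy, sxx, syy), r(sxz, sxx, szz), r(syz, syy, szz)
    den = (1 - rxz ** 2) * (1 - ryz ** 2)
    if den <= _DEGENERATE_TOL:
        return 0.0
    return float((rxy - rxz * ryz) / np.sqrt(den))


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _perm_inner_batch(a: np.ndarray, b_flat: np.ndarray, perms: np.ndarray,
                      block: int = 128) -> np.ndarray:
    """Inner products <a[perm][:, perm], b_k> for each permutation and each
    matrix in ``b_flat`` (m, n*n).  Returns (n_perm, m).

    Centering commutes with simultaneous row/col permutation, so gathering
    the centered matrix is exact.  float32 keeps memory traffic low; the
    observed statistic must be computed through the same path.
    """
    n = a.shape[0]
    a32 = np.ascontiguousarray(a, dtype=np.float32)
    out = np.empty((len(perms), b_flat.shape[0]), dtype=np.float32)
    # symmetry: <A_perm, B> = 2 <ut(A_perm), ut(B)> + <diag(A_perm), diag(B)>
    iu0, iu1 = np.triu_indices(n, 1)
    flat_idx = np.concatenate([iu0 * n + iu1, np.arange(n) * (n + 1)])
    n_ut = iu0.size
    half = np.empty((b_flat.shape[0], n_ut + n), dtype=np.float32)
    for k in range(b_flat.shape[0]):
        row = b_flat[k].take(flat_idx)
        row[:n_ut] *= 2.0
        half[k] = row
    for start in range(0, len(perms), block):
        chunk = perms[start:start + block]
        gathered = np.empty((len(chunk), n_ut + n), dtype=np.float32)
        for i, p in enumerate(chunk):
            gathered[i] = a32[p][:, p].ravel().take(flat_idx)
        out[start:start + block] = gathered @ half.T
    return out


def _draw_perms(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


def _pdcor_perm_stats(sxy: np.ndarray, sxz: np.ndarray, syz: float,
                      sxx: float, syy: float, szz: float) -> np.ndarray:
    """Vectorized pdcor over permuted <x,y> and <x,z> inner products."""
    rxy = sxy / np.sqrt(sxx * syy)
    rxz = sxz / np.sqrt(sxx * szz)
    ryz = syz / np.sqrt(syy * szz) if syy * szz > _DEGENERATE_TOL else 0.0
    den = (1 - rxz ** 2) * (1 - ryz ** 2)
    out = np.zeros_like(rxy)
    ok = den > _DEGENERATE_TOL
    out[ok] = (rxy[ok] - rxz[ok] * ryz) / np.sqrt(den[ok])
    return out


def dcor_pvalue(x, y, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for distance correlation:
    p = (1 + #{permuted stat >= observed}) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    a = double_center(_dist(x))
    b = double_center(_dist(y))
    if (a * a).mean() < _DEGENERATE_TOL or (b * b).mean() < _DEGENERATE_TOL:
        return 1.0
    rng = np.random.default_rng(seed)
    perms = _draw_perms(rng, len(x), n_perm)
    b32 = b.astype(np.float32).reshape(1, -1)
    obs = float(a.astype(np.float32).ravel() @ b32[0])
    stats = _perm_inner_batch(a, b32, perms)[:, 0]
    return float((1 + int((stats >= obs).sum())) / (n_perm + 1))


def _project_residual(a: np.ndarray, az: np.ndarray, szz: float) -> np.ndarray:
    """U-centered residual of ``a`` after projecting out ``az``."""
    beta = _u_inner(a, az) / szz
    return a - beta * az


def pdcor_pvalue(x, y, z, n_perm: int = 199, seed: int = 0) -> float:
    """Permutation p-value for pdcor(x, y; z).

    Projects the conditioning variable out of both U-centered matrices and
    permutes the indices of x's *residual* matrix; permuting raw x would
    test total rather than partial dependence and is badly anti-
    conservative whenever x and z are themselves associated.
    """
    x = np.asarray(x, float).ravel()
    ax = u_center(_dist(x))
    ay = u_center(_dist(np.asarray(y, float).ravel()))
    az = u_center(_dist(np.asarray(z, float).ravel()))
    n = len(x)
    szz = _u_inner(az, az)
    if szz <= _DEGENERATE_TOL:
        log.warning("pdcor_pvalue: degenerate z, falling back to dcor test")
        return dcor_pvalue(x, y, n_perm=max(n_perm, 99), seed=seed)
    px = _project_residual(ax, az, szz)
    py = _project_residual(ay, az, szz)
    spp = _u_inner(px, px)
    sqq = _u_inner(py, py)
    if min(spp, sqq) <= _DEGENERATE_TOL:
        return 1.0
    obs = _u_inner(px, py) / np.sqrt(spp * sqq)
    rng = np.random.default_rng(seed)
    perms = _draw_perms(rng, n, n_perm)
    py_flat = py.astype(np.float32).reshape(1, -1)
    inn = _perm_inner_batch(px, py_flat, perms)[:, 0] / (n * (n - 3))
    stats = inn / np.sqrt(spp * sqq)
    count = int((stats >= obs).sum())
    return float((1 + count) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Edge sign
# ---------------------------------------------------------------------------

def edge_sign(tf_expr, target_expr, min_cells: int = 10,
              rho_threshold: float = 0.1) -> str:
    """Sign of the Spearman correlation among TF-expressing cells; 'none'
    when fewer than ``min_cells`` expressing cells or |rho| < threshold."""
    tf_expr = np.asarray(tf_expr, float).ravel()
    target_expr = np.asarray(target_expr, float).ravel()
    on = tf_expr > 0
    if on.sum() < min_cells:
        return "none"
    rho = scipy.stats.spearmanr(tf_expr[on], target_expr[on]).statistic
    if not np.isfinite(rho) or abs(rho) < rho_threshold:
        return "none"
    return "positive" if rho > 0 else "negative"


# ---------------------------------------------------------------------------
# Network inference
# ---------------------------------------------------------------------------

@dataclass
class GRNEdge:
    tf: str
    target: str
    dcor: float
    p_value: float
    p_adj: float
    sign: str = "none"
    pruned_by: str | None = None

    @property
    def retained(self) -> bool:
        return self.pruned_by is None


@dataclass
class GRNResult:
    tissue: str
    population: str
    edges: list[GRNEdge] = field(default_factory=list)
    interactions: list[dict] = field(default_factory=list)
    n_cells: int = 0
    n_candidates: int = 0

    @property
    def retained_edges(self) -> list[GRNEdge]:
        return [e for e in self.edges if e.retained]

    @property
    def target_sets(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for e in self.retained_edges:
            out.setdefault(e.tf, set()).add(e.target)
        return out

    def positive_tfs(self) -> set:
        return {e.tf for e in self.retained_edges if e.sign == "positive"}


def _stream_seed(base: int, *labels) -> np.random.SeedSequence:
    keys = [zlib.crc32(str(v).encode()) for v in labels]
    return np.random.SeedSequence(entropy=int(base) % (2 ** 31), spawn_key=tuple(keys))


def infer_network(bundle: ExpressionBundle, panel: SeedPanel, tissue: str,
                  population: str, config: PipelineConfig) -> GRNResult:
    """Three-stage seed-TF network inference for one (tissue, population)."""
    if bundle.normalized is None:
        raise ValueError("normalized layer required; run lognormalize first")
    mask = ((bundle.cell_meta["tissue"] == tissue) &
            (bundle.cell_meta["population"] == population)).to_numpy()
    n = int(mask.sum())
    if n < 30:
        raise SampleSizeError(
            f"{tissue}/{population}: {n} cells < 30 required for inference")

    norm = bundle.normalized_dense()[mask]
    counts = bundle.counts_dense()[mask]
    seed_set = set(panel.seed_tfs)
    present_tfs = [t for t in panel.seed_tfs if t in set(bundle.gene_ids)]
    gene_pos = {g: i for i, g in enumerate(bundle.gene_ids)}

    detect_frac = (counts > 0).mean(axis=0)
    cand_names = [g for g in bundle.gene_ids
                  if g not in seed_set
                  and detect_frac[gene_pos[g]] >= config.candidate_min_detect_frac]
    result = GRNResult(tissue=tissue, population=population, n_cells=n,
                       n_candidates=len(cand_names))
    if not cand_names:
        return result

    # centered matrices; degenerate (constant) vectors are excluded
    tf_mats: dict[str, np.ndarray] = {}
    for t in present_tfs:
        m = double_center(_dist(norm[:, gene_pos[t]]))
        if (m * m).mean() > _DEGENERATE_TOL:
            tf_mats[t] = m
    cand_keep, cand_flat, cand_dvar = [], [], []
    for g in cand_names:
        m = double_center(_dist(norm[:, gene_pos[g]]))
        dv = (m * m).mean()
        if dv > _DEGENERATE_TOL:
            cand_keep.append(g)
            cand_flat.append(m.astype(np.float32).ravel())
            cand_dvar.append(dv)
    if not cand_keep or not tf_mats:
        return result
    b_flat = np.stack(cand_flat)  # (m, n*n) float32
    cand_dvar = np.array(cand_dvar)

    # ----- stage 1: dCor + permutation p, Holm per TF family --------------
    edges: list[GRNEdge] = []
    for tf_i, tf in enumerate(present_tfs):
        if tf not in tf_mats:
            continue
        a = tf_mats[tf]
        dva = (a * a).mean()
        a32_flat = a.astype(np.float32).ravel()
        obs = b_flat @ a32_flat  # unscaled dcov sums, (m,)
        rng = np.random.default_rng(
            _stream_seed(config.rng_seed, "stage1", tissue, population, tf))
        perms = _draw_perms(rng, n, config.n_permutations)
        stats = _perm_inner_batch(a, b_flat, perms)  # (n_perm, m)
        exceed = (stats >= obs[None, :]).sum(axis=0)
        pvals = (1 + exceed) / (config.n_permutations + 1)
        adj = holm_adjust(pvals, config.alpha)
        for j, g in enumerate(cand_keep):
            if adj.p_adj[j] < config.alpha:
                dcov2 = max(float(obs[j]) / (n * n), 0.0)
                dc = float(np.sqrt(dcov2 / np.sqrt(dva * cand_dvar[j])))
                edges.append(GRNEdge(tf=tf, target=g, dcor=min(dc, 1.0),
                                     p_value=float(pvals[j]),
                                     p_adj=float(adj.p_adj[j])))

    scale = n * (n - 3)
    # ----- stage 2: partial-dCor pruning via co-seeds sharing the target --
    # For each (TF a, co-seed b) the conditioner is projected out of a's
    # U-centered matrix once; permutations of that residual matrix are
    # gathered once and multiplied against the residual matrices of every
    # shared target in one GEMM.  All co-seeds are evaluated; pruned_by
    # records the first (iteration-order) co-seed that explains the edge.
    by_target: dict[str, list[GRNEdge]] = {}
    for e in edges:
        by_target.setdefault(e.target, []).append(e)
    u_cache: dict[str, np.ndarray] = {}

    def u_mat(g: str) -> np.ndarray:
        if g not in u_cache:
            u_cache[g] = u_center(_dist(norm[:, gene_pos[g]]))
        return u_cache[g]

    # pair_tests[(a, b)] = [(edge, target), ...]
    pair_tests: dict[tuple[str, str], list] = {}
    for target, tlist in by_target.items():
        if len(tlist) < 2:
            continue
        regs = [e.tf for e in tlist]
        for e in tlist:
            for b_tf in regs:
                if b_tf != e.tf:
                    pair_tests.setdefault((e.tf, b_tf), []).append((e, target))

    for (tf_a, b_tf), pairs in pair_tests.items():
        ax, az = u_mat(tf_a), u_mat(b_tf)
        sxx, szz = _u_inner(ax, ax), _u_inner(az, az)
        if min(sxx, szz) <= _DEGENERATE_TOL:
            continue
        px = _project_residual(ax, az, szz)
        spp = _u_inner(px, px)
        if spp <= _DEGENERATE_TOL:
            continue
        targets = [t for _, t in pairs]
        py_mats, keep_pairs, norms = [], [], []
        for e, t in pairs:
            ay = u_mat(t)
            syy = _u_inner(ay, ay)
            if syy <= _DEGENERATE_TOL:
                continue
            py = _project_residual(ay, az, szz)
            sqq = _u_inner(py, py)
            if sqq <= _DEGENERATE_TOL:
                continue
            py_mats.append(py.astype(np.float32).ravel())
            keep_pairs.append((e, t, ay, syy, sqq))
        if not py_mats:
            continue
        stack = np.stack(py_mats)
        px32 = px.astype(np.float32).ravel()
        obs_inner = (stack @ px32) / scale
        perm_inner = None
        for k, (e, target, ay, syy, sqq) in enumerate(keep_pairs):
            if e.pruned_by is not None:
                continue
            pd_obs = float(obs_inner[k]) / np.sqrt(spp * sqq)
            sxy = _u_inner(ax, ay)
            denom = sxx * syy
            r_uncond = sxy / np.sqrt(denom) if denom > _DEGENERATE_TOL else 0.0
            # compare on the same (bias-corrected, squared-dCor) scale as
            # the partial statistic, not the raw dCor scale
            pruned = pd_obs < config.pruning_drop_fraction * r_uncond
            if not pruned:
                if perm_inner is None:
                    rng = np.random.default_rng(
                        _stream_seed(config.rng_seed, "stage2", tissue,
                                     population, tf_a, b_tf))
                    perms = _draw_perms(rng, n,
                                        config.n_permutations_conditional)
                    perm_inner = _perm_inner_batch(px, stack, perms) / scale
                stats = perm_inner[:, k] / np.sqrt(spp * sqq)
                p = (1 + int((stats >= pd_obs).sum())) / \
                    (config.n_permutations_conditional + 1)
                pruned = p > config.alpha
            if pruned:
                e.pruned_by = b_tf
                result.interactions.append(
                    {"tf_a": e.tf, "tf_b": b_tf, "target": target})

    # ----- stage 3: signs --------------------------------------------------
    for e in edges:
        if e.retained:
            e.sign = edge_sign(counts[:, gene_pos[e.tf]],
                               norm[:, gene_pos[e.target]])
    result.edges = edges
    return result
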