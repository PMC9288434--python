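import numpy as np
import pytest

from hemorank.core_io import PipelineConfig, SeedPanel
from hemorank.grn import (SampleSizeError, dcor_pvalue, distance_correlation,
                          edge_sign, infer_network, partial_distance_correlation,
                          pdcor_pvalue)
from hemorank.preprocess import preprocess
from hemorank.synthdata import (ENDOTHELIAL, generate_cohort, indirect_chain_spec,
                                seed_mediator_chain_spec, TissueSpec)

from conftest import make_bundle

PANEL = SeedPanel()


# ---------------------------------------------------------------------------
# Brute-force oracles: explicit loops, no vectorized shortcuts
# ---------------------------------------------------------------------------

def brute_dcor(x, y):
    n = len(x)
    a = np.array([[abs(x[i] - x[j]) for j in range(n)] for i in range(n)])
    b = np.array([[abs(y[i] - y[j]) for j in range(n)] for i in range(n)])

    def center(d):
        out = np.empty_like(d, dtype=float)
        for i in range(n):
            for j in range(n):
                out[i, j] = (d[i, j] - d[i, :].mean() - d[:, j].mean() + d.mean())
        return out

    A, B = center(a), center(b)
    dcov2 = sum(A[i, j] * B[i, j] for i in range(n) for j in range(n)) / n ** 2
    dvx = sum(A[i, j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    dvy = sum(B[i, j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy))


def brute_u_center(d):
    n = d.shape[0]
    out = np.zeros_like(d, dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            out[i, j] = (d[i, j]
                         - d[i, :].sum() / (n - 2)
                         - d[:, j].sum() / (n - 2)
                         + d.sum() / ((n - 1) * (n - 2)))
    return out


def brute_pdcor(x, y, z):
    n = len(x)

    def dmat(v):
        return np.array([[abs(v[i] - v[j]) for j in range(n)] for i in range(n)])

    A, B, C = (brute_u_center(dmat(v)) for v in (x, y, z))

    def inner(p, q):
        return sum(p[i, j] * q[i, j] for i in range(n) for j in range(n)) / (n * (n - 3))

    def r(p, q):
        d = inner(p, p) * inner(q, q)
        return inner(p, q) / np.sqrt(d) if d > 0 else 0.0

    rxy, rxz, ryz = r(A, B), r(A, C), r(B, C)
    den = (1 - rxz ** 2) * (1 - ryz ** 2)
    if den <= 0:
        return 0.0
    return (rxy - rxz * ryz) / np.sqrt(den)


class TestDistanceCorrelation:
    def test_self_dependence_is_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert distance_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_affine_dependence_is_one(self):
        x = np.array([0.0, 1, 2, 3])
        assert distance_correlation(x, 3 * x + 7) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 61)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            assert distance_correlation(x, y) == pytest.approx(brute_dcor(x, y),
                                                               abs=1e-10)

    def test_shift_scale_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        d0 = distance_correlation(x, y)
        assert distance_correlation(2.5 * x + 1, y) == pytest.approx(d0, abs=1e-12)
        assert distance_correlation(x, 0.1 * y - 4) == pytest.approx(d0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert distance_correlation(x, y) == pytest.approx(
            distance_correlation(y, x), abs=1e-14)

    def test_constant_vector_is_degenerate_zero(self):
        x = np.ones(10)
        y = np.arange(10.0)
        val, degenerate = distance_correlation(x, y, return_degenerate=True)
        assert val == 0.0 and degenerate


class TestPartialDistanceCorrelation:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(6, 40))
            x = rng.normal(size=n)
            z = rng.normal(size=n)
            y = 0.5 * x + 0.5 * z + rng.normal(size=n)
            assert partial_distance_correlation(x, y, z) == pytest.approx(
                brute_pdcor(x, y, z), abs=1e-10)

    def test_independent_z_preserves_dependence(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        val = partial_distance_correlation(x, x, z)
        assert val > 0.9

    def test_symmetric_in_x_y(self):
        rng = np.random.default_rng(9)
        x, y, z = rng.normal(size=(3, 40))
        assert partial_distance_correlation(x, y, z) == pytest.approx(
            partial_distance_correlation(y, x, z), abs=1e-14)

    def test_degenerate_z_falls_back_to_dcor(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=(2, 30))
        z = np.ones(30)
        assert partial_distance_correlation(x, y, z) == pytest.approx(
            distance_correlation(x, y), abs=1e-12)


class TestPermutationPvalues:
    def test_identical_vectors_minimal_p(self):
        x = np.arange(12.0)
        assert dcor_pvalue(x, x, n_perm=999, seed=0) == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 60))
        assert dcor_pvalue(x, y, 199, seed=5) == dcor_pvalue(x, y, 199, seed=5)

    def test_degenerate_input_p_one(self):
        assert dcor_pvalue(np.ones(20), np.arange(20.0), 99, 0) == 1.0

    def test_superuniform_under_independence(self):
        """Rejection rate at alpha=0.05 within Monte-Carlo error of 0.05."""
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 200
        for i in range(reps):
            x, y = rng.normal(size=(2, 60))
            if dcor_pvalue(x, y, 199, seed=1000 + i) <= 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate < 0.05 + 3 * se

    def test_chain_conditioning_attenuates_dependence(self):
        """TF -> mediator -> target chains: conditioning on the mediator
        removes most of the TF-target dependence (pdcor is far below the
        unconditional level and below the pruning threshold)."""
        from hemorank.synthdata import generate_tissue
        from hemorank.grn import u_distance_correlation
        ratios, pds = [], []
        for i in range(10):
            spec = indirect_chain_spec(n_cells=400)
            counts, meta, _ = generate_tissue(spec, seed=100 + i, panel=PANEL)
            genes = (list(PANEL.seed_tfs) + spec.module_genes()
                     + [f"Hk{k+1}" for k in range(spec.n_housekeeping_genes)]
                     + [f"Bg{k+1:03d}" for k in range(spec.n_background_genes)])
            gi = {g: j for j, g in enumerate(genes)}
            x = np.log1p(counts[:, gi["Fli1"]])
            z = np.log1p(counts[:, gi["Tmed"]])
            y = np.log1p(counts[:, gi["Tchain"]])
            marginal = u_distance_correlation(x, y)
            pd = partial_distance_correlation(x, y, z)
            pds.append(pd)
            ratios.append(pd / marginal)
        assert np.mean(pds) < 0.15
        assert np.mean(ratios) < 0.5  # below the pruning drop fraction

class TestEdgeSign:
    def test_identical_positive(self):
        x = np.arange(1.0, 31)
        assert edge_sign(x, x) == "positive"

    def test_decreasing_negative(self):
        x = np.arange(1.0, 31)
        assert edge_sign(x, -x + 100) == "negative"

    def test_independent_mostly_none(self):
        rng = np.random.default_rng(13)
        nones = 0
        for _ in range(20):
            tf = rng.integers(1, 10, size=500).astype(float)
            tgt = rng.normal(size=500)
            if edge_sign(tf, tgt) == "none":
                nones += 1
        assert nones >= 15

    def test_too_few_expressing_cells_none(self):
        tf = np.zeros(50)
        tf[:5] = 1.0
        assert edge_sign(tf, np.arange(50.0)) == "none"


class TestInferNetwork:
    def test_small_population_errors(self):
        counts = np.ones((10, 12), dtype=int)
        b = make_bundle(counts, gene_ids=list(PANEL.seed_tfs) + ["t1"],
                        normalized=True)
        with pytest.raises(SampleSizeError):
            infer_network(b, PANEL, "t0", ENDOTHELIAL, PipelineConfig())

    def test_seed_mediated_edge_pruned(self):
        """Fli1 drives Gata2 which drives the target: the indirect
        Fli1->target edge carries pruned_by=Gata2."""
        spec = seed_mediator_chain_spec(n_cells=300)
        bundle, _ = generate_cohort([spec, indirect_chain_spec(300)], seed=21,
                                    panel=PANEL)
        cfg = PipelineConfig(rng_seed=21)
        b = preprocess(bundle, cfg, PANEL)
        res = infer_network(b, PANEL, "seedchain", ENDOTHELIAL, cfg)
        retained = {(e.tf, e.target) for e in res.retained_edges}
        assert ("Gata2", "Tchain") in retained
        fli_edges = [e for e in res.edges if e.tf == "Fli1" and e.target == "Tchain"]
        assert fli_edges and fli_edges[0].pruned_by == "Gata2"
        assert any(i["tf_a"] == "Fli1" and i["tf_b"] == "Gata2" and
                   i["target"] == "Tchain" for i in res.interactions)

    def test_deterministic_given_seed(self):
        spec = seed_mediator_chain_spec(n_cells=120)
        bundle, _ = generate_cohort([spec, indirect_chain_spec(120)], seed=3,
                                    panel=PANEL)
        cfg = PipelineConfig(rng_seed=3)
        b = preprocess(bundle, cfg, PANEL)
        r1 = infer_network(b, PANEL, "seedchain", ENDOTHELIAL, cfg)
        r2 = infer_network(b, PANEL, "seedchain", ENDOTHELIAL, cfg)
        e1 = [(e.tf, e.target, e.p_value, e.pruned_by) for e in r1.edges]
        e2 = [(e.tf, e.target, e.p_value, e.pruned_by) for e in r2.edges]
        assert e1 == e2
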