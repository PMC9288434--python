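# Methods

## Scope and data model

`hemorank` compares endothelial populations across tissues by how
completely they express the regulatory program of the
endothelial-to-hematopoietic transition (EHT). All analyses run on an
`ExpressionBundle`: a sparse cells × genes count matrix with per-cell
annotations (tissue, population, dataset) and, after normalization, a
log-normalized layer of identical shape. "Expressed"/"detected" always
means raw count > 0; detection frequencies, co-expression counts and the
Runx1⁺/Runx1⁻ split all use this convention, which matches how dot-plot
frequency statistics are normally computed.

## Preprocessing

Genes are kept when detected in strictly more than
`filter_min_cells_per_gene` (default 10) cells; seed-panel genes are
exempt, because a low-frequency TF must never be dropped before the
frequency analysis that is the point of the pipeline. Cells are kept when
they detect at least `filter_min_genes_per_cell` genes (default 0; the
threshold is a config value chosen by inspecting the per-cell
detected-gene histogram the filter returns, not an automatic valley
detector — automating it would invent a rule the data do not define).
Normalization is global scaling:
`normalized = ln(1 + count / cell_total × scale)` with scale 10 000.
The gene-then-cell filter pair is idempotent, and normalization is
monotone within each cell, which is all the rank- and detection-based
statistics downstream require. Variance-stabilizing UMI-specific
normalizations are out of scope; every statistic the pipeline computes
(detection masks, ranks, distance correlations of a monotone transform)
is insensitive to which monotone per-cell normalization is used.

## Seed-TF panel statistics

For every (tissue, population) group, each of the 11 seed TFs gets its
detection fraction and its mean normalized expression among expressing
cells (dot-plot semantics), with a moderate/low class assigned at the
25% detection threshold. Co-expression summarizes, per cell, the number
k of co-detected TFs from the 8-TF sub-panel (*Cbfb, Erg, Fli1, Gata2,
Lmo2, Lyl1, Runx1, Tal1*); the distribution is reported as exact counts
and at-least-k fractions together with k* = the largest k co-expressed
by at least half the cells. Because published summaries sometimes count
over a different panel width, the same table is also emitted for the
full 11-TF panel; neither is privileged.

## Network inference

The dependence measure is the Székely–Rizzo sample distance correlation
on normalized expression: pairwise |·| distance matrices are
double-centered and dCor = dCov/√(dVarₓ·dVar_y). It is zero (in the
population) exactly under independence and detects non-monotone
dependence, which matters for saturating regulatory responses.

*Stage 1.* For each seed TF and each candidate target (non-seed genes
detected in ≥ 10% of the analyzed population — rank/distance statistics
are meaningless on near-all-zero vectors, and the bound also limits the
size of each multiple-testing family), the permutation p-value is
p = (1 + #{permuted statistic ≥ observed}) / (n_perm + 1) with
n_perm = 999. P-values are Holm-adjusted within each TF's candidate
family and edges with adjusted p < α = 0.05 are kept. Note the
arithmetic this forces: with 999 permutations the smallest achievable
raw p is 1/1000, so a Holm family larger than ~49 candidates could never
produce a significant edge; the candidate rule (and the synthetic gene
space) keeps families near 40.

*Stage 2.* For each kept edge (a, t) and each co-seed b that also has a
kept edge to t, the bias-corrected (U-centered) partial distance
correlation pdcor(a, t; b) is compared with the unconditional U-centered
statistic R*(a, t): the edge is pruned (and a TF–TF interaction {a, b, t}
recorded) when conditioning removes at least half the dependence
(pdcor < 0.5·R*) or kills its significance. The comparison is made on
the U-centered scale on both sides — R* is a squared-dCor-scale
quantity, and mixing it with raw dCor would prune systematically.
Conditioning is restricted to co-seed TFs: the design is seed-centric,
and conditioning on arbitrary genes would change the question being
asked. The pruning significance test permutes the indices of the
U-centered *residual* matrix (a's matrix after projecting b's out), the
approach used by the reference implementations of the partial distance
covariance test. Permuting raw a instead would test total rather than
partial dependence and is badly anti-conservative whenever a and b are
associated — exactly the indirect-chain situation the stage exists for.
This test only needs resolution around α, so it runs with
`n_permutations_conditional` = 199 rather than 999.

*Stage 3.* Retained edges are signed by the Spearman correlation between
TF and target restricted to TF-expressing cells: positive/negative when
|ρ| ≥ 0.1 with at least 10 expressing cells, otherwise "none".

Permutation statistics are evaluated in float32 through a batched
gather-plus-GEMM path (double- and U-centering commute with simultaneous
row/column permutation, and the centered matrices are symmetric, so only
the upper triangle and diagonal enter the inner product); the observed
statistic is computed through the same float32 path so the comparison is
internally consistent. Reported dCor values are float64. All permutation
streams derive deterministically from `rng_seed` plus stable labels
(tissue, population, TF), so inference is reproducible and independent
of evaluation order.

## Activity scoring

Per tissue, genes are ranked within each cell from highest to lowest
normalized expression, ties (including the zero block) broken by a
seeded random shuffle. For a target set, the recovery curve walks the
top L = ⌊top_fraction × n_genes⌋ ranks accumulating set hits; its area,
normalized by the maximum achievable (the whole set, capped at L, at the
very top), is the cell's AUC in [0, 1]. `auc_top_fraction` defaults to
0.05, the conventional recovery-curve cap. The active/inactive threshold
comes from a two-component Gaussian mixture on the AUC values: when the
component means separate by more than twice the pooled SD, the threshold
is the equal-posterior point between them; otherwise the 99th percentile
is used and flagged "unimodal" (a seeded, automatic stand-in for
choosing thresholds by inspecting bimodality). Significance is a
per-cell two-group Kruskal–Wallis test of set vs background rank values
— since each cell's ranks are an exact permutation of 1..G there are no
ties and the statistic has a closed form with a χ²(1) null — followed by
Holm correction across cells. A cell is assigned to a program when it
passes both the threshold and the significance gate.

A consequence worth knowing: with two groups the maximum attainable KW
statistic is ≈ 3·|set| regardless of the number of genes, so a target
set needs roughly six members before *any* cell can survive Holm
correction across a few hundred cells. Small programs therefore
contribute to the network score only through the overlap clique, not
through per-cell assignment; this is a property of the chosen per-cell
test, not of the data.

## Overlaps, signatures, ranking

Pairwise target-set overlaps are reported as symmetric intersection
counts and row-normalized fractions |Tᵢ∩Tⱼ|/|Tⱼ|; the "clique" is the
largest TF subset in which every pair overlaps reciprocally at ≥ 50%,
found by exhaustive subset search (≤ 2¹¹ subsets). Counts are the primary
quantity; the 50% reciprocal rule is the only quantified anchor available
for "high overlap" and is configurable.

Runx1⁺ signatures: endothelial cells with Runx1 count > 0 form one group
(both groups must have ≥ 3 cells — a tissue without Runx1⁺ endothelium
raises an informative error and is recorded as such); markers are genes
with Holm-adjusted two-sided rank-sum p < α and log fold-change > 0.25
(difference of mean log-normalized expression) in the positive group.
The rank-sum + Holm + fold-change gate is a deliberately simple,
fully testable marker rule. Markers recurring in at least
`recurrence_min_tissues` = 4 tissues form the cross-tissue signature.

The composite rank per tissue averages three max-normalized components:
mean seed-TF detection frequency in endothelium; mean co-detected
sub-panel fraction per endothelial cell; and a network score
0.5·(n_pos/11) + 0.5·(clique/11), where n_pos counts TFs with a retained
positive edge whose target set is assigned to at least one endothelial
cell. Equal weights are the simplest aggregation consistent with
"normalize to maximum, then rank" and are configurable in code. Ties are
broken deterministically (frequency score, then tissue name) and
flagged.

## Synthetic cohorts

The generator plants known structure at desk scale:

* **Seed-TF expression**: per cell, on/off ~ Bernoulli(detection
  frequency); "on" counts are 1 + NB(mean 8, dispersion 15). The planted
  frequency is therefore the exact detection probability — it is the
  ground truth the frequency and co-expression scores are validated
  against, so dropout is applied to non-seed genes only (a TF's planted
  frequency already folds capture efficiency in).
* **Regulation**: a target's NB mean is
  `baseline × exp(s(Σ sign·effect·z_tf))` over its regulators, with z
  the standardized log1p TF expression and s a tanh saturation at ±4 log
  units (a saturating transcriptional response that keeps means finite
  and dependence monotone). Shared-module edges use effect 0.7 (eight
  regulators sum on one target), private edges 1.2.
* **Chains**: tf → mediator → target with no direct term; and a seed-TF
  mediator variant in which one TF's expression level drives another's
  (`tf_couplings`), creating the indirect edge the pruning stage must
  remove.
* **Noise**: NB dispersion 15 and Bernoulli dropout 0.05 on non-seed
  genes — the regime of a high-sensitivity full-length protocol, which
  is the data regime this style of network inference needs. Three
  high-abundance "housekeeping" genes (NB mean 400, dispersion 50)
  anchor per-cell totals, standing in for the panel-external bulk of a
  real library; without them the per-cell normalization divides the
  shared-module signal by itself (in real data totals are dominated by
  thousands of unrelated genes, so this compositional cancellation is
  negligible). 140 rare background genes (means 0.005–0.05) populate the
  ranking without entering the ≥10% candidate family; 5 dense background
  genes and the housekeeping genes do enter it, keeping each Holm family
  at ~40 candidates.

The default cohort has six tissues in planted order: an embryo-like
tissue (all TF frequencies 0.90, a full eight-TF shared-target module
with private targets, one repressive edge, n = 500 endothelial cells),
three graded adult-like tissues (brain > kidney > liver: shrinking
frequencies, shrinking module cliques of 6/4/3 TFs, each with a small
Runx1 program so Runx1⁺ markers recur in ≥ 4 tissues; n = 250), a
pancreas-like tissue whose endothelium has *no* Runx1 expression but
whose leukocyte population (n = 150) carries a Fli1/Runx1 shared module
(the white-blood-cell confound the overlap analysis must localize), and
a null tissue (frequencies 0.05, no edges). The true tissue order is
defined by construction as mean endothelial TF frequency × (1 + number
of endothelially active planted edges), which is monotone along this
list. Effect sizes, dispersions and population sizes were calibrated
once, before the acceptance checks were frozen, so that planted edges
sit clearly above the permutation null at these sample sizes; they are
the stated study conditions, not tuning knobs.

What the generator does **not** emulate: library-size gradients, batch
effects, doublets, correlated TF co-regulation (TFs are independent
given their frequencies — deliberate, because a shared latent activity
factor would make every module edge "explained" by its co-seeds and the
pruning stage would correctly remove the whole module), and a realistic
20 000-gene transcriptome. Passing tests therefore demonstrate that the
statistics behave as specified under controlled conditions, not that the
pipeline's biological conclusions transfer to any particular real atlas.

## Numerical and degenerate-input choices

Constant vectors have zero distance variance; dCor is defined as 0 there
(flagged), permutation p-values as 1, and degenerate conditioning
variables fall back to the unconditional statistic with a warning.
Populations under 30 cells refuse network inference; target sets smaller
than two genes are skipped by activity scoring (the two-group rank test
needs both groups). Mixture fits use 5 seeded initializations with a
small covariance floor. Holm adjustment returns both the exact stepwise
significance flags and the standard monotone adjusted p-values.

## Known limitations

* Partial distance correlation does not characterize conditional
  independence: even for a weak linear Gaussian chain x → z → y the
  population pdcor(x, y; z) is slightly positive, and at large n the
  residual-permutation test detects this higher-order remainder. The
  pruning stage is therefore built on *attenuation* (conditioning
  removes ≥ half the dependence) with the significance test as a
  secondary guard, and the package's tests assert the attenuation
  property rather than exact conditional-independence calibration.
* Per-cell Kruskal–Wallis + Holm across cells has no power for target
  sets below ~6 genes (see above).
* With 999 permutations, Holm families above ~49 candidates cannot yield
  any significant edge; analyses of gene spaces with many more dense
  candidates would need more permutations or a different error-rate
  strategy.
* The composite ranking's equal component weights and the 50% reciprocal
  clique rule are conventions; both are exposed in code and flagged in
  reports.
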