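# mtis

**Multi-Target Integration Score: ZINB-autoencoder latent scoring of a
gene set's activity in single-cell transcriptomes.**

Medicinal plants act on diseases through many targets at once, so their
effect on a tissue is not visible in any single gene. `mtis` condenses the
per-cell expression of a *common-target* gene set — the genes shared
between a plant's pharmacological target list and a disease's associated
genes — into one number per cell, the **Multi-Target Integration Score
(MTIS)**, and provides the downstream analyses that score supports:
group and cell-type comparisons, differential-gene testing along
pseudotime and along the score itself, network-constrained key-gene
selection, and a classifier benchmark of the encoding. A synthetic-data
generator makes the whole pipeline runnable and testable without any
download.

The audience is computational biologists working on network-pharmacology
questions over single-cell RNA-seq data (the motivating system is
hawthorn acting on the perivascular adipose tissue of atherosclerosis,
with three patient groups: control, early-stage, advanced).

## The model

Let `CG` be the `N x Q` count matrix of the `Q` common-target genes in
`N` cells. A five-layer autoencoder maps each cell through a 64-neuron
encoding layer, a **one-neuron middle layer**, and a 64-neuron decoding
layer:

    Dc = ReLU( ReLU( ReLU( f_norm(CG) W_Ec ) W_M ) W_Dc )

with `f_norm` = size-factor division (total counts over the median
total), log1p, and per-gene z-scoring. Three output heads map `Dc` to the
parameter matrices of a zero-inflated negative binomial per entry —
mean `K = s_c * exp(Dc W_k)`, dispersion `R = exp(Dc W_r)`, dropout
`P = sigmoid(Dc W_p)` — and the training loss is the mean ZINB negative
log-likelihood of the raw counts:

    ZINB(x; mu, theta, pi) = pi * 1{x=0} + (1 - pi) * NB(x; mu, theta)

Training runs 300 epochs of Adam at learning rate 0.001 in mini-batches
of 32 with validation-based early stopping. After training, the scalar
activation of the middle layer is the cell's MTIS: a learned,
noise-model-aware one-dimensional summary of the target program. An
alternative `literal` head mode exposing the exponential-dropout-as-odds
parameterization, and a linear bottleneck, are selectable.

Downstream, per-gene expression change along a covariate (pseudotime or
MTIS) is tested with a negative binomial log-link GLM on a natural cubic
spline basis (df = 3) against the intercept-only model (likelihood-ratio
chi-squared), with Benjamini-Hochberg q values. Genes in both top-50
lists (CTPMs) that have >= 2 high-confidence (score >= 0.7) interaction
partners among the common targets, plus the co-most-significant genes,
are reported as key mediating genes.

## Worked example

```python
import mtis
from scipy.stats import spearmanr

cfg = mtis.SimConfig(cells_per_group=100, n_genes=20, n_target_genes=10, seed=0)
cg, ann, truth = mtis.simulate_dataset(cfg)

est = mtis.MTISEncoder(random_state=0).fit(cg)   # 300-epoch budget, early stop
table = est.mtis_table(cg)                       # cell_id, mtis

print(len(est.loss_history_), round(est.loss_history_[-1], 3))
print(round(spearmanr(table["mtis"], truth.activity).statistic, 3))

comparisons, summaries = mtis.group_celltype_summary(table, ann)
print(comparisons[comparisons["scope"] == "all-cells"]
      [["group_a", "group_b", "statistic", "p_value"]].to_string(index=False))
```

prints

```
139 2.561
-0.896
group_a  group_b  statistic      p_value
control    early    13473.0 6.140378e-17
control advanced    14923.0 1.109137e-32
  early advanced    13599.0 4.307356e-18
```

The model stopped after 139 epochs at a mean ZINB negative log-likelihood
of 2.561; the per-cell MTIS tracks the simulator's latent target-program
activity at |Spearman rho| = 0.90 (the sign of a one-neuron latent is
arbitrary); and the z-scaled scores separate all three simulated disease
stages by Wilcoxon rank-sum test.

The same pipeline runs from files via the CLI:

```bash
mtis simulate --preset smoke --outdir data/
mtis all --counts data/counts --targets data/targets.csv \
         --annotations data/annotations.tsv --network data/network.tsv \
         --outdir run/ --seed 7
```

which writes `model.json`, `mtis.csv`, `comparisons.csv`,
`summaries.csv`, `de_pseudotime.csv`, `de_mtis.csv`, `keygenes.json`,
`benchmark.csv` and a `run_manifest.json` sufficient to re-execute the
run exactly.

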