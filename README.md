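# survgate

Attention-gated dual-branch neural survival classification for gene-expression
cohorts, with the full surrounding pipeline: chi-square feature screening with
Benjamini–Hochberg FDR control, k-means grouping of genes and patients
(including subsampled consensus clustering), focal-loss training, and a
survival evaluation suite (Kaplan–Meier, log-rank, Cox proportional hazards,
ROC and time-dependent ROC).

The package targets the prognosis-from-transcriptome setting typified by
neuroblastoma microarray cohorts: a genes × samples expression matrix, a
clinical table with overall-survival time and vital status, and the question
of whether a patient's expression profile predicts survival. Because the
public cohorts this design comes from require external downloads, the package
ships a first-class synthetic-cohort generator that plants two
survival-associated gene modules (one protective, one adverse) with known
ground truth, so every stage is testable end to end.

## The model

Expression values are min–max normalized per gene,
`f' = (f − min f)/(max f − min f)`. Genes are screened against the binary
survival label with the "frequency" chi-square statistic (per-class value
sums as observed counts, class-size-proportional expectations, 1 df) and kept
at FDR < 0.05; k-means splits the retained genes into two groups g₁, g₂.

Each group is encoded by a two-layer ReLU network into a 10-dimensional code:

    g₁' = f(W₁₂ f(W₁₁ g₁ + b₁₁) + b₁₂)        f = ReLU
    g₂' = f(W₂₂ f(W₂₁ g₂ + b₂₁) + b₂₂)

The two codes are fused by a sigmoid attention gate — each branch modulates
the other elementwise —

    G = [σ(g₂') ⊙ g₁' , σ(g₁') ⊙ g₂']

and a two-layer decoder produces the death probability
`y' = σ(w₃₂ f(W₃₁ G + b₃₁) + b₃₂)`. Patients with y' < 0.5 are called alive,
otherwise dead. Training minimizes the focal loss

    L = −α (1−y')^γ log y'         (y = 1, dead)
    L = −(1−α) y'^γ log(1−y')      (y = 0, alive)

with α = 0.2, γ = 2 (down-weighting the easy majority class), Adam at
learning rate 0.01, glorot-uniform initialization, 20% inverted dropout on
every hidden layer, and early stopping on a 10% validation holdout. The
network, its analytic gradients and the optimizer are plain numpy; gradients
are verified against central finite differences in the test suite.

Evaluation includes accuracy/sensitivity/specificity/F1, ROC AUC, the
Kaplan–Meier-weighted cumulative/dynamic time-dependent ROC at 3/5/10-year
horizons, log-rank contrasts between k-means patient subgroups, univariable
and multivariable Cox regression (Newton–Raphson, Breslow ties), and a
repeated stratified 10-fold cross-validation harness.

## Worked example

Simulate a high-signal cohort, fit, and evaluate (the `survgate` console
script is equivalent to `python -m survgate.cli`):

```bash
survgate simulate --out demo/sim --n-samples 400 --n-genes 300 \
    --n-informative-g1 20 --n-informative-g2 40 --effect-size 4.0 \
    --hr-subgroup 30.0 --risk-coupling 0.3 --censor-rate 0.3 --seed 7
survgate fit --expression demo/sim/expression.tsv \
    --clinical demo/sim/clinical.tsv --out demo/fit --seed 1
survgate evaluate --model demo/fit/model.json \
    --expression demo/sim/expression.tsv \
    --clinical demo/sim/clinical.tsv --out demo/eval
```

prints

```
simulated 400 samples x 300 genes (278 events) -> demo/sim
selected 57 genes (groups 17/40); test AUC 0.817 -> demo/fit
n=400 accuracy=0.637 AUC=0.842 -> demo/eval
```

The fit step screened 57 of 300 genes at FDR < 0.05 against vital status
(hitting planted module genes), grouped them 17/40, trained on a 70% split
and reached AUC 0.817 on the held-out 30% (5-year time-dependent ROC AUC
0.883). The evaluation report adds the k-means patient subgroups (log-rank
p ≈ 8e-71 between them) and the Cox table, where the binarized model
probability stays significant alongside age, MYCN status, stage and risk —
the model carries prognostic information not explained by the clinical
covariates. All artifacts are JSON/TSV under the `--out` directories.

`survgate crossval` runs the 20×10-fold cross-validation summary and
`survgate cluster` the 1000-replicate consensus clustering; both accept the
same inputs.

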