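# phenonet

Phenotype-guided miRNA–mRNA network discovery from blood multi-omics data.

Single-feature association testing routinely misses regulatory structure:
a miRNA that weakly tracks a phenotype can still be a hub of a
phenotype-associated regulatory network. `phenonet` implements the
network-first alternative for two omics blocks and a quantitative
phenotype — scaled sparse multiple canonical correlation analysis (SmCCA)
with feature subsampling — as a tested, reproducible pipeline aimed at
computational biologists working with cohort blood expression data
(e.g. lung-function or emphysema phenotypes in COPD cohorts).

## The method

With mRNA block X1, miRNA block X2 and phenotype Y (columns standardized),
canonical weight vectors maximize

```
J(w1, w2) = a·cov(X1w1, X2w2) + b·cov(X1w1, Y) + c·cov(X2w2, Y),
            ‖wk‖₂ ≤ 1,  ‖wk‖₁ ≤ lk·√pk
```

with unequal scaling weights (a, b, c) so the systematically weaker
miRNA–phenotype correlations are not drowned out by the mRNA block.
The pipeline around the solver:

1. **Preprocess** counts: remove extreme-count outlier features
   (single read > 5M), filter absent/low-variance features, upper-quartile
   normalize, remove residual-derived unwanted variation, and apply a
   closed-form negative-binomial variance-stabilizing transform.
2. **Adjust** omics and phenotype for covariates under a named regime
   (`none`, `partial` = sex/age/race, `full` = + smoking and WBC
   percentages).
3. **Network**: average |wᵢwⱼ| over subsampled fits (70% of mRNAs, 90% of
   miRNAs per repetition) into a robust adjacency matrix; extract modules
   by average-linkage clustering; sign edges by expression correlation.
4. **Prune** each module over an edge-threshold grid (0.001 steps),
   selecting the trimmed network that maximizes |cor(PC1, phenotype)|.
5. **Evaluate**: fraction of negatively correlated miRNA–mRNA pairs found
   in an offline target database, overlap with a published miRNA list
   (with 3p/5p arm expansion), and comparison against per-feature
   Pearson + Benjamini–Hochberg single-omics testing.
6. **Enrich** network genes with classic and conditional
   (child-gene-removal) Fisher tests over a term DAG.

Because the cohorts this method targets are access-restricted, the package
includes a seeded synthetic-cohort generator with planted
miRNA–mRNA–phenotype modules (negative-binomial counts, library-size,
batch and covariate effects, hemolysis-like outliers) that serves as both
the demonstration dataset and the ground truth for the test suite. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (seed 1); each writes its tables under `results/`.
Running `python analysis/04_prune_evaluate.py` prints:

```
 module  n_features  threshold  n_nodes  n_mirna  n_mrna  abs_cor  p_value
      1         358      0.001       62       22      40   0.7091      0.0
top network: module 1, tau=0.001, 40 mRNA + 22 miRNA nodes, |cor(PC1, phenotype)| = 0.7091 (p = 3.88e-47)
planted-node recovery F1 of the top network: 0.894
              metric   n  found  rate_pct
 predicted_pair_rate 683    152 22.254758
 validated_pair_rate 683    198 28.989751
published_mirna_rate  22     19 86.363636
```

Reading this: out of 358 features surviving preprocessing, pruning the
detected module at edge threshold 0.001 keeps a 62-node network whose
expression PC1 correlates at |r| = 0.709 with the phenotype. The network
recovers the 70 planted features with F1 = 0.894. Of its 683 negatively
correlated miRNA–mRNA pairs, 29% appear as validated entries in the target
database — against a ~0.1% baseline over all possible pairs — and 19 of
its 22 miRNA nodes are in the planted ("published") miRNA list.

The same pipeline is scriptable:

```python
from phenonet import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=1, reps=100))
top = bundle.networks[0]
print(top.threshold, top.pc1_correlation)
```

or drivable from the shell: `phenonet run-all --seed 1 --out-dir results/run`
(subcommands: `simulate`, `preprocess`, `adjust`, `run-all`,
`compare-regimes`).

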