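# cropboost

Genomic selection for hybrid crop breeding with gradient-boosted trees.

Hybrid breeding programs organised as a North Carolina-II design — a pool
of inbred maternal lines crossed factorially with a panel of inbred
paternal testers — can generate far more F1 combinations than anyone can
phenotype (1428 mothers × 30 testers is already 42,840 hybrids).
`cropboost` is a toolkit for predicting F1 phenotypes from genome-wide
SNP markers in that setting, for breeders and quantitative geneticists
who want to rank un-phenotyped crosses, design condensed marker panels,
and understand how prediction accuracy depends on how the training set
covers the candidates' parents.

The core predictor is a from-scratch **leaf-wise gradient-boosted tree
engine**: each boosting iteration grows one asymmetric tree by repeatedly
splitting only the leaf whose best split has the highest second-order
gain

    gain = G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ),

with leaf weights −G/(H+λ). The gain accumulated at each marker's splits,
summed over all trees, is its **information-gain (IG) importance**, which
drives marker-panel design. Around the engine the package provides:

- `geno` — PLINK .ped/.map and VCF input, MAF/missingness filtering, the
  additive 0/1/2 coding and a frequency-free ten-state coding of ordered
  base pairs, and F1 genotype inference from inbred parents;
- `popstruct` — PCA, OPTICS and k-means views of population structure;
- `pheno` — within-family z-scores, general combining ability
  (GCAᵢ = X̄ᵢ − X̄), and quantile class labels;
- `gbdt` — the boosting engine (regression, binary, multiclass) with
  grid-search tuning;
- `baseline` — a ridge marker-effect model (rrBLUP-style) with REML
  shrinkage estimation, the standard linear comparator;
- `harness` — parent-coverage predictive frameworks (MP / M / P /
  neither), sampling-rate scenarios, Pearson-r and AUC evaluation,
  IG marker-panel selection with random-panel controls, a single-marker
  association scan, and prediction-augmented association mapping;
- `simpop` — an NC-II population simulator with known QTL architecture
  that generates every input the rest of the toolkit consumes.

## Worked example

Simulate a 6210-hybrid evaluation population (207 maternal lines × 30
testers), encode the F1 genotypes, and compare the booster with the ridge
baseline under a 5:1 random split:

```python
import numpy as np
from cropboost import geno, gbdt, harness, simpop

cfg = simpop.SimConfig(n_maternal=207, n_testers=30, n_markers=500,
                       n_qtl=20, h2=0.5, seed=42)
pop = simpop.simulate_population(cfg)
enc = geno.encode_additive(pop.f1)
y = pop.phenotypes.values[:, 0]

plans = [harness.split_by_parent_coverage(pop.pedigree, "random",
                                          test_fraction=1/6, seed=s)
         for s in range(5)]
for name, spec in [("gbdt", ("gbdt", {"n_iterations": 60, "max_leaves": 15,
                                      "min_samples_leaf": 10})),
                   ("ridge", ("ridge", {"lam": "reml"}))]:
    rep = harness.evaluate_regression(spec, enc, y, plans)
    print(f"{name}: mean r = {rep.mean:.3f}")

model = gbdt.fit(enc, y, n_iterations=60, max_leaves=15,
                 min_samples_leaf=10)
imp = gbdt.feature_importance(model)
top = imp.top(5)
hits = len(set(top) & set(pop.truth["qtl_idx"]))
print(f"top-5 IG markers, true QTL among them: {hits}")
```

Output:

```
gbdt: mean r = 0.672
ridge: mean r = 0.679
top-5 IG markers, true QTL among them: 5
```

Mean r is the Pearson correlation between predicted and measured
phenotypes on the held-out sixth of the population, averaged over five
random splits — at h² = 0.5 the best achievable r is about √0.5 ≈ 0.71,
and both models sit close to it, with the linear model slightly ahead on
this mostly-additive trait. All five of the highest-IG markers are true
simulated QTL.

The same pipeline is available from the shell:

```bash
cropboost sim --seed 42 --n-maternal 207 --n-testers 30 --out pop/
cropboost geno --in pop/f1.ped --format ped --encode additive012 --out enc.tsv
cropboost fit --in enc.tsv --pheno pop/phenotypes.tsv --trait trait --out model.json
cropboost importance --model model.json --top 384 --out panel.tsv
```

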