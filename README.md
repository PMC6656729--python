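# slowfast

Tools for asking whether trait syndromes — the leaf economics spectrum (LES)
and the whole-plant slow-fast continuum (SFC) — have diverged among natural
lineages of a selfing plant by more than genetic drift alone can explain.
The package is aimed at evolutionary ecologists working with panels of
inbred accessions (the motivating system is *Arabidopsis thaliana*) that
combine dense SNP genotyping, replicated greenhouse phenotyping and
climate-of-origin data.

## What it computes

**Genetic differentiation.** Accessions are assigned to lineages from an
ancestry-fraction (Q) matrix using a strict majority rule (> 50% of the
genome from one cluster, otherwise "Admixed" and excluded). Because the
panel is fully homozygous, every genome is treated as haploid and the
Weir–Cockerham F_ST estimator reduces to a one-way ANOVA of 0/1 allele
indicators per SNP:

    theta = a / (a + b),   a = (MSP - MSG) / n_c,   b = MSG

with among-/within-population mean squares MSP, MSG and the unbalanced-design
coefficient n_c. Multilocus F_ST is the ratio of sums Σa / Σ(a+b) (the
unweighted per-SNP mean is also reported). Per-SNP significance comes from
permuting population labels (default 1,000 permutations, 95th-quantile rule),
and the *neutral F_ST* benchmark is the median of the significant,
intergenic per-SNP values. Sliding-window LD pruning (r² < 0.1 within 50 kb)
and a realized-relationship kinship matrix round out the module.

**Phenotypic differentiation.** For each trait or axis, genotype means are
decomposed into between-/within-population variance components and converted
to the Q_ST surrogate for autogamous species:

    P_ST = c σ²_B / (c σ²_B + h² σ²_W)

with **no** factor 2 on σ²_W (offspring of a selfer inherit the whole
genotype). Under H0: c = h² = 1 this is directly comparable to neutral F_ST.
A parametric bootstrap (default 10,000 iterations) gives the 95% CI; the
verdict is "diversifying" when the CI lower bound exceeds neutral F_ST. A
sensitivity analysis sweeps the c/h² ratio and reports the *critical c/h²* —
the smallest ratio at which the verdict would hold.

**Traits and axes.** Rosette growth series are fitted with a 3-parameter
logistic; RGR is the relative growth rate at the inflection, analytically
r/2. LES and SFC axes are PC1 of a correlation-matrix PCA of
log10-transformed genotype means (RGR stays on its natural scale), oriented
so high scores = conservative/slow. Leaf-to-plant trait scaling uses
standardized major axis (SMA) regression with the correlation-based slope
CI, and a kinship-aware GLS check guards trait–trait slopes against
population structure.

**Climate.** Pearson correlation screen of axis scores against bioclim-style
variables, bidirectional stepwise-AIC model selection, repeated k-fold
cross-validated predictive r² (selection re-run inside every training fold),
and linear prediction over a climate grid with extrapolation flags.

**Synthetic data.** `slowfast.synthetic` generates all of the above —
Balding–Nichols genotypes with a target F_ST and admixed accessions,
replicated phenotypes with specified (σ²_B, σ²_W, c, h²), logistic growth
series, and climate tables coupled to a trait score — so the entire pipeline
is testable without any external download.

## Worked example

```python
import numpy as np
from slowfast import (assign_populations, fst_analysis, heritability,
                      pst_analysis, trait_means_wide)
from slowfast.synthetic import (SimGenoParams, SimPhenoParams,
                                simulate_genotypes, simulate_phenotypes)

g, q = simulate_genotypes(SimGenoParams(n_snps=2000, fst_target=0.1, seed=1))
labels = assign_populations(q)          # strict >50% rule; rest "Admixed"

fst = fst_analysis(g, labels, n_perm=1000, seed=2)
print(round(fst.multilocus["theta_ratio_of_sums"], 3))   # 0.098
print(round(fst.neutral_fst, 3))                         # 0.094

t = simulate_phenotypes(SimPhenoParams(sigma2_B=3.5, sigma2_W=6.5,
                                       h2_true=0.6, seed=3), labels)
h2 = heritability(t, "trait")
res = pst_analysis(trait_means_wide(t)["trait"], labels,
                   neutral_fst=fst.neutral_fst, h2=h2, seed=4)
print(round(res.pst, 2), [round(v, 2) for v in res.ci])  # 0.45 [0.08, 0.7]
print(res.critical_ratio, res.verdict)                   # 1.3 not-distinguishable
```

The simulated panel is moderately differentiated (multilocus θ̂ ≈ 0.098
against the target 0.10) and the neutral benchmark sits just below it. The
trait was generated with a plug-in between-population share of 0.35; with
only five lineages both the point estimate (0.45 in this draw) and the
bootstrap interval are wide, so the H0 verdict is inconclusive and the
sensitivity analysis reports the c/h² ratio (1.3 here) at which the
diversifying call would become robust.

A YAML-driven CLI wraps the same steps
(`slowfast simulate|fst|pst|axes|climate --config config.yaml`).

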