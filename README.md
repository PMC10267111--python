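# symptomnet

Network analysis of comorbid depressive symptoms, suicidality and
hypothalamic–pituitary–adrenal (HPA) axis biomarkers, as applied to
psychiatric-emergency cohorts: mixed-type correlation estimation,
regularised Gaussian graphical models, centrality and bridge-symptom
analysis, bootstrap stability diagnostics and permutation-based network
comparison — together with a synthetic cohort generator that makes every
stage testable against a known ground truth.

## Who this is for

Researchers analysing participant-by-item psychiatric data of mixed type —
ordinal rating-scale items (e.g. the 24-item Hamilton Depression Rating
Scale, items scored 0–4), binary indicators (current suicidal ideation,
plan, attempt) and continuous biomarkers (ACTH in pg/ml, cortisol in
nmol/L) — who want the full estimation-to-stability pipeline of the
psychometric-network literature in Python, with reproducible seeds and
tested numerics.

## The model

Observed variables are modelled as manifestations of a latent multivariate
Gaussian **Z** ~ N(0, Σ). Ordinal and binary items are discretised latent
normals, so pairwise latent correlations are estimated by two-step maximum
likelihood: polychoric (ordinal × ordinal; tetrachoric for binary pairs),
polyserial (ordinal × continuous) and Pearson (continuous × continuous).
The assembled matrix **S** (repaired to positive-semidefinite by eigenvalue
clipping) feeds a sparse Gaussian graphical model: the graphical lasso

  Θ̂(λ) = argmax  log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|

is fitted along a logarithmic path from λ_max down, each candidate edge set
is scored by the Extended Bayesian Information Criterion

  EBIC(E) = −2 ℓ̂(E) + |E| log n + 4 γ |E| log p,    γ = 0.5,

with ℓ̂(E) the support-constrained maximum likelihood, and the network
reported is that constrained MLE — partial correlations
w_ij = −Θ_ij / √(Θ_ii Θ_jj) on the selected support.

On the estimated network the package computes node strength Σ|w|, expected
influence (EI, the signed sum Σw), bridge expected influence (signed sum of
edges leaving a node's community), shortest-path betweenness on distances
1/|w|, focal-node "predictive betweenness" (shortest paths anchored at a
designated node, ACTH by default), the focal-node flow view, case-dropping
bootstrap stability summarised by the CS-coefficient, nonparametric
bootstrap edge CIs and difference tests, and a permutation Network
Comparison Test (M = maximum edge difference, S = global-strength
difference) between two subgroups.

## Worked example

```python
import numpy as np
from symptomnet import (
    default_study_cohort, mixed_matrix, ebic_glasso,
    centrality_table, strongest_edges, prevalence_ci,
)

table, truth = default_study_cohort(n=898, seed=1)   # 29 variables
nodes = [c for c in table.values.columns if c != "HAMD3"]
corr = mixed_matrix(table.values[nodes],
                    type_map={k: v for k, v in table.type_map.items()})
net = ebic_glasso(corr, n=table.n,
                  communities={k: table.communities[k] for k in nodes})
print(f"{net.p} nodes, {len(net.edge_list())} edges")
print("strongest edge:", strongest_edges(net, 1)[0])
cent = centrality_table(net, focal="ACTH")
print("top EI node:", cent["expected_influence"].idxmax())
print("SI prevalence:", prevalence_ci(int(table.values.SI.sum()), table.n))
```

prints

```
28 nodes, 87 edges
strongest edge: ('SI', 'SP', 0.5045230120860397)
top EI node: SI
SI prevalence: (32.63, 29.56, 35.69)
```

— a 28-node network (item 3 of the depression scale is excluded as
redundant with the SI indicator), whose strongest edge sits inside the
suicidality triad — note it exceeds the generating partial correlation
because dropping item 3, which loads on SI, re-routes its shared variance
into SI's remaining edges — and a suicidal-ideation prevalence near the
31% the generator targets, with its 95% Wald interval in percent.

A thin CLI mirrors the stages:

```bash
symptomnet simulate --n 898 --seed 1 --out cohort.csv
symptomnet estimate cohort.csv --out edges.tsv
symptomnet centrality cohort.csv --focal ACTH --out centrality.tsv
symptomnet report --seed 1 --out report.json
```

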