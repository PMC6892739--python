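# pediascore

Phenotype-driven prioritization of exome candidate genes that combines
molecular and next-generation-phenotyping evidence. In the diagnostic
workup of rare monogenic disease, an exome yields hundreds of rare,
plausibly deleterious variants; clinical features encoded as Human
Phenotype Ontology (HPO) terms and computer-assisted analysis of
frontal facial photographs each narrow the field, but none of the
three evidence levels alone is decisive. `pediascore` integrates five
per-gene scores into a single ranking score:

| column | evidence | source |
| --- | --- | --- |
| `cadd` | deleteriousness of the gene's top variant (CADD-PHRED) | exome, per-gene max after rare-variant filtering |
| `gestalt` | facial-gestalt similarity to the gene's syndromes | per-syndrome photo-similarity vector, mapped to genes |
| `feature_match` | clinical-feature overlap | ancestor-closure Jaccard between patient and disease HPO terms |
| `phenomizer` | semantic similarity | symmetric Resnik best-match-average over term information content |
| `boqa` | Bayesian ontology query | posterior over diseases under a false-positive/false-negative noise model |

Each candidate gene of a case is a point x in this five-dimensional
score space. A soft-margin linear SVM with decision function
f(x) = w·x̃ + b (x̃ standardized per feature) is trained on pooled
gene rows, causal genes labelled positive, with inverse-frequency
class weighting and the regularization strength C selected from
{2⁻⁶, …, 2¹²} by internal fivefold cross-validation on top-1
accuracy. The signed hyperplane margin f(x) — the **PEDIA score** —
ranks the genes of a held-out case. Benchmarking uses *gene-disjoint*
tenfold cross-validation (all cases sharing a causal gene occupy one
fold) on spike-in exomes: the causal variant's score is inserted into
a healthy background exome so the truth is known.

Because real cohorts of this kind (patient photos, pathogenic
variants) are not redistributable, the package ships a synthetic
cohort generator that emulates every input — a rooted phenotype DAG,
disease annotations, noisy patient queries, gestalt vectors with
tunable signal, per-ethnicity background exomes — so the whole
pipeline is testable and benchmarkable offline. See
`docs/methods.md` for the model and generator details.

## Worked example

```python
from pediascore import (
    SyntheticConfig, generate_cohort, ClassifierConfig,
    cross_validate, train_model, weight_contributions,
)

cohort = generate_cohort(SyntheticConfig(n_cases=200, n_diseases=20, seed=1))
report = cross_validate(cohort, ClassifierConfig(seed=1), k=10, seed=1)
print("top-1 :", report.topk[1])
print("top-10:", report.topk[10])

model = train_model(list(cohort.tables.values()), ClassifierConfig(seed=1))
print(weight_contributions(model))
```

prints

```
top-1 : 0.98
top-10: 1.0
{'variant': 0.1337..., 'features': 0.3881..., 'gestalt': 0.4781...}
```

top-1 = 0.98 means the causal gene ranked first in 98% of the 200
held-out cases; the contribution map splits the summed absolute SVM
weights across the variant-level, HPO-feature-level and photo-level
evidence. On this synthetic cohort the CADD-only baseline
(`ablation_grid(cohort, [("cadd",)], ...)`) reaches only ~0.49 top-1:
the phenotype columns carry most of the discrimination, mirroring the
motivation for integrating them.

The same run is available from the shell:

```sh
pediascore simulate --seed 1 --out run/
pediascore evaluate --cases run/cases --tables run/tables.json \
    --folds 10 --seed 1 --out run/eval
```

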