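# guttype

Enterotype clustering, alpha diversity and correlation-network analysis for
gut-microbiota cohort studies, together with a synthetic-cohort generator
that reproduces the statistical structure such studies assume.

## Who this is for

Microbiome researchers analysing 16S amplicon count tables at the family (or
any other) rank who want the classic distance-based enterotyping workflow —
Jensen-Shannon divergence, partitioning around medoids, Calinski-Harabasz
k-selection, prediction-strength and silhouette validation — plus the
standard cohort statistics (Welch's t, Mann-Whitney U, Fisher's exact, Holm
correction, compact letter displays, Kendall tau-b networks, lean/obese BMI
stratification) as one tested, scriptable package.

## The model at the core

Samples are compared with the square root of the Jensen-Shannon divergence

d(a, b) = √( H((a+b)/2) − (H(a) + H(b))/2 ),   H(p) = −Σᵢ pᵢ ln pᵢ,

a metric bounded by √(ln 2). The cohort is partitioned with PAM (k-medoids)
directly on this distance matrix; k is chosen by maximizing the
Calinski-Harabasz index in the principal-coordinates embedding, and the
chosen partition is validated with

* **prediction strength (PS)** — split-half stability: the worst-case
  fraction of held-out within-cluster pairs that are co-assigned when
  classified by the training half's medoids (PS ≥ 0.9 ⇒ strong clustering);
* **silhouette index (SI)** — mean of (b−a)/max(a,b) (SI ≤ 0.25 ⇒ no
  substantial structure, 0.25–0.5 weak, 0.5–0.75 reasonable, > 0.75 strong).

A partition is called *statistically reliable* when PS ≥ 0.9 and SI > 0.25.

The synthetic generator draws each sample from a mixture of community
archetypes: composition ~ Dirichlet(concentration × archetype mean), reads ~
Multinomial at a Normal library depth (default 10,252 ± 2,406, clamped at
100). Ordinal questionnaire items are tied to chosen families through a
Gaussian copula calibrated by Greiner's relation τ = (2/π)·arcsin(ρ).

## Worked example

```python
from guttype.simulate import default_config, generate_cohort
from guttype.abundance import to_relative, prevalence
from guttype.clustering import jsd_distance, select_and_validate
from guttype.pipeline import stratify

config = default_config(seed=42)          # 516 subjects, 66 families
cohort = generate_cohort(config)
rel = to_relative(cohort.counts)

print("mean % Bacteroidaceae:", round(100 * rel.data["Bacteroidaceae"].mean(), 1))
print("prevalence % Prevotellaceae:", round(100 * prevalence(cohort.counts)["Prevotellaceae"], 1))

males = stratify(cohort.metadata, "gender")["male"]
dist = jsd_distance(rel.subset(males))
report = select_and_validate(dist, range(2, 11), repeats=100, seed=42)
print("male stratum: best_k =", report.best_k,
      "PS =", round(report.prediction_strength, 2),
      "SI =", round(report.silhouette, 2),
      "->", report.ps_class, "/", report.si_class,
      "| reliable:", report.reliable)
```

prints

```
mean % Bacteroidaceae: 33.2
prevalence % Prevotellaceae: 72.9
male stratum: best_k = 2 PS = 1.0 SI = 0.35 -> strong clustering / weak structure | reliable: True
```

The first two lines are cohort-level composition summaries (the generator's
default archetypes center the dominant family near a third of reads, and
Prevotellaceae is detected in roughly three-quarters of subjects). The last
line is the cluster-validation verdict for the male stratum: the
Calinski-Harabasz index selects two clusters, the split-half prediction
strength clears the strong-clustering bound, and the silhouette falls in the
weak-structure band — a reliable but weakly partitioned pair of
enterotype-like clusters.

The same stages are available from the shell:

```bash
guttype simulate --seed 1 --n-samples 200 --out cohort/
guttype cluster --counts cohort/counts.tsv --seed 2 --out validation.tsv
guttype diversity --counts cohort/counts.tsv --out diversity.tsv
guttype run --seed 1 --out full_run/        # every stage, with a manifest
```

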