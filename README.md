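# sestrat

Non-genetic tumor stratification from super-enhancer RNA (seRNA) activity.

Super-enhancers (SEs) are large clusters of enhancers whose transcriptional
output — seRNA — tracks their regulatory activity. In lung adenocarcinoma,
tumors fall into reproducible subgroups ("SE hetero-programming clusters")
defined not by mutations but by which SEs are active; the worst-prognosis
subgroup is marked by abnormal SE activation, elevated aerobic glycolysis,
and a small set of driver transcription factors. `sestrat` implements that
analysis as a tested, reusable pipeline:

1. **Consensus clustering** of the seRNA matrix (resampled K-means;
   consensus(i,j) = co-clustering frequency among resamples containing both
   samples) with the number of clusters chosen by PAC minimization
   (PAC = F(0.9) − F(0.1) of the consensus CDF).
2. **Cluster-specific SEs** by one-vs-rest Wilcoxon rank-sum on log2
   activity (q ≤ 0.05, log2FC ≥ 1).
3. **SE → gene linkage**: genes whose TSS lies within 500 kb of a
   cluster-specific SE and whose mRNA correlates with the seRNA
   (Spearman ρ ≥ 0.3, BH q ≤ 0.05, positive sign) — the SE-regulated
   potential genes (SPGs).
4. **SE-regulated genes**: SPGs intersected with the cluster's directed DEG
   set, overlap tested by one-sided Fisher's exact test.
5. **Core TFs**: promoter motif enrichment (PWM log2-odds scanning, both
   strands, Fisher + BH) nominates candidate TFs; per-cluster one-vs-rest
   LASSO-penalized logistic regression (coordinate descent, 10-fold CV,
   1-SE rule) selects each cluster's core TF as the top-|weight| nonzero
   coefficient.
6. **Multi-TF index**: the worst-prognosis cluster's intercept-free linear
   predictor on standardized log2 TF expression — a per-sample scalar used
   for prognosis (Kaplan–Meier / log-rank at the median split) and cluster
   prediction (argmax over the per-cluster models).
7. **Signature scoring**: single-sample mean z-score over a gene set (e.g.
   a 22-gene glycolysis signature) to phenotype the clusters.

A built-in synthetic-cohort generator (`sestrat.generate_cohort`) plants all
of this structure — cluster-specific SE activation, correlated SE→gene
links within the genomic window, driver-TF motifs in target promoters,
cluster-dependent survival hazards — with complete ground-truth
bookkeeping, so the whole pipeline is testable without any data download.

## Worked example

```python
import numpy as np
from sestrat import CohortConfig, generate_cohort, fit_core_tfs, build_tf_index
from sestrat.pipeline_runner import PipelineInputs, run_all
from sestrat.io_formats import DEFAULT_CONFIG

cohort = generate_cohort(CohortConfig(seed=1, n_samples=150))
cfg = dict(DEFAULT_CONFIG, n_resamples=100)
report = run_all(PipelineInputs.from_cohort(cohort), cfg, seed=1, outdir="out")
print(report["chosen_k"], report["core_tfs"], report["index_cluster"])
print(report["logrank"]["clusters"]["p"])
print(report["signature_scores"]["mean_by_cluster"])
```

prints

```
3 {1: 'TF03', 2: 'TF01', 3: 'TF02'} 1
5.104367343921918e-14
{1: 0.618144194028561, 2: -0.30725588769463696, 3: -0.3108883063339239}
```

The pipeline re-discovers the three planted clusters (`chosen_k = 3`;
discovered cluster numbers are arbitrary — here discovered cluster 1 is the
planted high-hazard cluster, so its core TF is the planted worst-cluster
driver `TF03` and it is chosen as the index cluster). The three-group
log-rank p-value shows the clusters separate survival, and the planted
glycolysis-like signature scores highest in the worst-prognosis cluster.

The same stages are exposed as a CLI:

```bash
sestrat simulate --outdir data --seed 1
sestrat run-all --indir data --outdir out --seed 1
```

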