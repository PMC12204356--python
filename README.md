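# foldpool

A toolkit for the *non-neural* computational core of an integrative protein
tertiary-structure prediction pipeline: scoring, ranking and selecting
predicted models from large AlphaFold-era model pools, CASP-style Z-score
evaluation of predictors, domain-based MSA engineering for multi-domain
targets, and divide-and-conquer stitching of overlapping region models.

It is aimed at structural bioinformaticians who already *have* predicted
models (from AlphaFold2/AlphaFold3/ESMFold or anything else emitting CA
coordinates) and external quality-assessment scores, and need the machinery
around them: reproducible similarity matrices, consensus scores, clustering,
top-5 selection strategies, and assessor-style evaluation — all testable
against synthetic pools with known ground truth, with no downloads and no
neural networks.

## What it computes

**Structural similarity** (CA-based, between models of one target, matched by
residue number):

- **GDT-TS** = mean over cutoffs d ∈ {1, 2, 4, 8} Å of the maximal fraction
  of corresponding CA atoms that a rigid superposition brings within d.
  The superposition search enumerates every residue subset for chains of
  ≤ 10 corresponded residues (exact) and otherwise uses an LGA-style
  seed-and-refine heuristic (contiguous windows of 3/5/7 + the global set,
  within-cutoff refinement, iterative trimming) that is a provable lower
  bound of the enumeration optimum.
- **TM-score** = max over superpositions of (1/L) Σᵢ 1/(1 + (dᵢ/d₀)²), with
  d₀ = 1.24·(L−15)^⅓ − 1.8 floored at 0.5 Å and L the target length, so
  missing residues contribute zero.

**Consensus and selection** (`foldpool.ranking`):

- **PSS** (pairwise similarity score): a model's mean similarity to every
  other model in the pool — the consensus quality estimate.
- QA-score normalization (plDDT/100) and weighted combination.
- K-means clustering of models embedded by their dissimilarity profiles,
  with silhouette-selected k.
- Four deterministic top-5 selection strategies: plDDT ranking with a
  TM < 0.8 structural-diversity constraint (`plddt_diverse`), per-cluster
  best-by-GATE representatives (`gate_cluster`), AF3-ranking top-1 with
  GATE+plDDT blend for the rest (`combined_llm`), and a multi-metric slot
  rota (`multicom_ensemble`) — each with a forced-AF3-inclusion rule where
  the strategy prescribes it and per-slot provenance strings.

**Assessor-style evaluation** (`foldpool.casp_eval`): per-domain two-pass
Z-scores of predictor GDT-TS (standardize, drop z < −2 outliers, re-standardize
over survivors), positive-only accumulation across domains, and averaging of
alternative-conformation domain pairs.

**MSA engineering** (`foldpool.msa`): A3M I/O, per-residue alignment depth
profiles, and domain-based MSA construction — per-domain alignments paired
across domains by shared sequence identifiers, gap-padded when unpaired, and
stacked under the full-length alignment (full / paired / unpaired blocks).

**Stitching** (`foldpool.assembly`): merge independently predicted,
overlapping region models into one full-length model by rigid superposition
on the shared residues, with per-junction RMSD diagnostics.

**Synthetic fixtures** (`foldpool.synthetic`): deterministic generators for
clustered model pools with known quality ordering (including a
minority-correct-cluster regime), MSAs with controlled per-region depth and
identifier overlap, and GDT-TS score panels with injected outliers.

## Worked example

A 20-model pool where 80% of the models share a wrong fold (a hinge-deformed
copy of the target) and only 20% are correct — the regime where consensus
scoring fails and clustering rescues the selection:

```python
import numpy as np
from foldpool import (PoolRecipe, make_pool, pairwise_matrix, pss,
                      cluster_models, select_top5)

recipe = PoolRecipe(L=60, n_models=20, cluster_fractions=(0.8, 0.2),
                    correct_cluster=1, noise_sigma=0.5, qa_noise=0.02, seed=7)
pool, truth = make_pool(recipe)
mat = pairwise_matrix(pool, metric="tm")

top = pss(mat).sort_values(ascending=False)
print("PSS top-1:", top.index[0], round(top.iloc[0], 3),
      "| cluster:", truth.labels[pool.model_ids.index(top.index[0])])
print("truly best model:", pool.model_ids[int(np.argmax(truth.true_tm))],
      "| true TM:", round(truth.true_tm.max(), 3))

cl = cluster_models(mat, k=2, seed=0)
res = select_top5("gate_cluster", pool, truth.qa_table, mat, cl)
print("gate_cluster top5:", res.top5)
```

prints

```
PSS top-1: m002 0.772 | cluster: 0
truly best model: m018 | true TM: 0.916
gate_cluster top5: ['m017', 'm000', 'm019', 'm005', 'm018']
```

The consensus score (PSS 0.772) crowns a model from the dominant wrong-fold
cluster 0, while the truly best model (TM 0.916 to the reference) sits in the
minority cluster — and the cluster-representative strategy still places
minority models (m017, m018, m019) in its top 5.

The same operations are available from the shell:

```bash
foldpool simulate --kind pool --seed 7 --out pool/ -L 60 --n-models 20
foldpool similarity --manifest pool/manifest.json --out sim.tsv
foldpool rank --matrix sim.tsv --table pool/qa_table.tsv --out ranked.tsv
foldpool select --strategy gate_cluster --table ranked.tsv --matrix sim.tsv \
                --manifest pool/manifest.json --out top5.json
foldpool evaluate --panel panel.csv --out-csv zscores.csv
foldpool stitch --manifest regions.json --out full.pdb
```

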