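# diseasomics

Integrative transcriptomics for linking a target disease to its risk
factors through shared gene dysregulation.

Many chronic diseases — cardiomyopathy is the motivating case — have
lifestyle and physiological risk factors (ageing, smoking, obesity,
insulin resistance, diet, alcohol, depression) whose molecular connection
to the disease is unclear. One way to probe that connection is to ask:
*which genes are differentially expressed both in disease-affected tissue
and in tissue affected by each risk factor?* `diseasomics` implements that
analysis as a reusable, tested package for case/control expression cohorts:

1. **DEG calling** — per condition, each gene is tested case vs control
   with an unpaired pooled-variance Student *t*-test on log2 intensities
   (`df = n₁ + n₂ − 2`, two-sided *p*), *p*-values are Benjamini–Hochberg
   adjusted, and a gene is a DEG when `p_adj < 0.05` and `|log2 FC| > 1`
   (both strict; log2 FC = difference of case and control means on the
   log2 scale).
2. **Diseasome networks** — the target's up- and down-regulated DEG sets
   are intersected with each risk factor's (direction-matched by default),
   producing bipartite condition–gene networks plus a multiway report of
   genes dysregulated in ≥ *m* conditions.
3. **Characterisation of the shared genes** —
   over-representation against GMT gene-set libraries
   (exact upper-tail hypergeometric `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`,
   BH within each library); degree-based hub ranking of the PPI subnetwork
   induced on the shared genes (STRING-style weighted edge lists, default
   confidence ≥ 0.4); TF/miRNA regulator ranking by number of distinct DEG
   targets in bipartite regulator→target tables; drug–target lookup; and
   gene–disease association of each factor's DEGs against a known disease
   gene list (hypergeometric, BH across the batch of factors).

A synthetic-data module (`diseasomics.synthdata`) generates every input
with planted ground truth — expression cohorts with a designed
cross-condition DEG overlap, a scale-free PPI with planted hubs, a library
with one planted enriched term, regulator/drug/disease tables — so the
whole pipeline is testable end to end without any external downloads.

## Worked example

Simulate a 5-condition workspace (one target, four risk factors, 1200
genes, 10 vs 10 samples, 60 planted DEGs per condition with a designed
overlap) and run the full pipeline:

```sh
diseasomics simulate demo --seed 11 --n-conditions 5 --n-genes 1200
diseasomics run-all demo/config.yaml
```

```
workspace written to demo (5 conditions)
pipeline complete: 20 artifacts, manifest written
```

`demo/results/diseasome/pairs.tsv` then holds the pairwise intersection —
for this seed the target shares 15, 11, 6 and 4 DEGs with the four factors,
exactly the planted design:

```
target  factor  n_up  n_down  n_shared  shared_up  shared_down
TARGET  RF1     0     15      15                   G0001,G0002,...,G0015
TARGET  RF2     0     11      11                   G0013,G0014,...,G0023
```

`demo/results/network/hubs.tsv` ranks the proteins of the PPI subnetwork
induced on the 33 distinct shared genes; the planted hub `G0001` is rank 1
with degree 19:

```
protein  degree  rank
G0001    19      1
G0005    14      2
```

The manifest (`demo/results/manifest.json`) records per-condition DEG
counts (e.g. TARGET: 16 up, 44 down), the planted enriched term `T000` as
the top enrichment hit, the planted regulators `TF00` and `mir-00-5p` at
rank 1, four drugs touching the shared genes, and a sha256 hash of every
artifact — rerunning the same config yields byte-identical hashes.

Every stage is also available on its own (`diseasomics deg`, `diseasome`,
`enrich`, `hubs`, `regulators`, `drugs`, `associate`) over saved
intermediates, and as plain library functions
(`diseasomics.call_degs`, `intersect_pair`, `enrich`, `rank_hubs`, ...).

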