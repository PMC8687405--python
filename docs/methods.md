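# Methods

## Statistical model

**Differential expression.** For each gene the case and control samples are
compared with an unpaired two-sample Student *t*-test with pooled variance:
`t = (x̄₁ − x̄₂) / √(s²ₚ(1/n₁ + 1/n₂))` with
`s²ₚ = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)`, `df = n₁ + n₂ − 2`, and a
two-sided *p*-value from the *t* distribution. The pooled (rather than
Welch) form is used deliberately: it is the classical "unpaired Student
t-test" of the microarray literature and matches the small-cohort setting
the package targets. Variances use the sample (n−1) convention throughout.

Testing happens on the **log2 scale**. Raw intensities are transformed as
`log2(x + offset)` (offset default 1.0, guarding zeros); `log2 FC` is then
the difference of group means, so the DEG threshold `|log2 FC| > 1` means
"more than two-fold change in geometric-mean intensity". Per-gene z-scoring
(`(g − mean(g))/SD(g)`, sample SD) is provided for cross-dataset comparison
output only and is never applied before fold-change computation — a
fold-change threshold has no meaning on unit-variance rows. A per-sample
z-score variant exists behind `axis="sample"` but is not the default.

Multiple testing uses **Benjamini–Hochberg** (step-up, FDR-controlling),
the field default for microarray DEG lists. Significance requires
`p_adj < α` **and** `|log2 FC| > lfc`, both strict inequalities, with
defaults α = 0.05, lfc = 1.0. Genes with zero pooled variance are excluded
from testing and reported explicitly, never silently dropped or NaN-filled.

**Probe collapsing.** When several rows map to one symbol, either the probe
with the largest |t| is kept (`max_abs_t`, default — it preserves the most
informative probe for the downstream test) or rows are averaged (`mean`).
Cross-platform gene identity is exact symbol match after uppercasing; no
identifier-conversion service is consulted, but an explicit probe→symbol
map can be supplied per condition.

**Diseasome intersection.** The target's and each factor's significant sets
are intersected direction-consistently by default (up∩up, down∩down),
because the up- and down-regulated diseasomes are built as separate
networks; a symbol-only mode is available. In the bipartite network for one
direction, condition nodes are the target plus every factor, gene nodes are
the genes of that direction shared between the target and ≥1 factor, and a
condition–gene edge means the gene is a direction-matched DEG of that
condition that is also shared with the target. An empty network is a valid
result (returned with a warning). The multiway report lists genes that are
DEGs in ≥ m conditions (default m = 2), sorted by multiplicity then symbol.

**Enrichment.** Over-representation of a query set against a term is the
exact upper-tail hypergeometric probability P(X ≥ k) with population N
(universe), K marked (term ∩ universe), n drawn (query ∩ universe) — the
one-sided Fisher convention of enrichment web services, computed exactly
(no normal approximation). BH adjustment spans all terms of one library;
libraries are corrected independently, mirroring how per-category term
tables are usually reported. The default universe is the library's union
intersected with the genes actually measured in the contributing datasets
(falling back to the library union); the choice is recorded in output.
Gene–disease association uses the same statistic with the disease gene
list as the term, BH-adjusted across the batch of risk factors; each
factor's full DEG set is the query.

**Network analysis.** Hubs are ranked by degree in the PPI subnetwork
*induced* on the query genes (both endpoints must be query genes; this is
the strict reading of "a network around the DEG-encoded proteins", and a
first-neighbour expansion is available behind a flag, default off). PPI
edge weights are STRING-style confidences in [0,1] — values above 1 are
auto-detected as 0–1000 combined scores and divided by 1000 — with a
default retention threshold of 0.4, STRING's medium-confidence convention.
Regulators (TFs, miRNAs) are scored by the number of *distinct* DEGs among
their known targets, i.e. bipartite degree restricted to the DEG set; this
is the only topological score consistent with reporting a short top list
from regulator→target tables. Rankings are deterministic: score
descending, then symbol ascending; ties at the cut are reported in full
and flagged (competition ranks). Drug lookup retains every drug with ≥1
query-gene target, keeping only those edges.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | adjusted-p threshold for DEG calls |
| `lfc` | 1.0 | log2 fold-change threshold (two-fold) |
| `log2_offset` | 1.0 | offset in `log2(x + offset)` (intensity units) |
| `collapse_method` | `max_abs_t` | probe→gene collapsing rule |
| `ppi_threshold` | 0.4 | minimum PPI confidence retained |
| `hub_k` | 10 | hub list length |
| `regulator_top_n` | 5 | regulator list length |
| `min_conditions` | 2 | multiway-report multiplicity floor |
| `direction_consistent` | true | up∩up / down∩down intersection |
| `neighbor_expansion` | false | include first neighbours before induction |

`hub_k = 10` and `regulator_top_n = 5` follow the customary lengths of
published hub-protein and regulator tables for this kind of analysis.

## Synthetic data: what it emulates, and what it does not

`simulate_condition_family` draws per-gene baselines lognormally (normal on
the log2 scale, default mean 8, SD 1.5 — typical microarray intensity
spread) and adds i.i.d. Gaussian noise (SD 0.5 log2 units) per sample;
planted DEGs shift the case mean by ±2 log2 units by default. Defaults are
2000 genes and 10 vs 10 samples — desk-scale stand-ins for cohort studies,
not full-platform sizes. The overlap design plants shared DEGs either as
pairwise-exclusive blocks (a symmetric count matrix) or as explicit
multi-condition blocks (a mapping of condition tuples to counts); shared
genes get the same direction in every condition of their block, matching
the directional split of the diseasome networks. Feasibility (block sums
within each condition's DEG budget) is checked up front.

The PPI generator grows a preferential-attachment (Barabási–Albert) graph
and raises designated hubs until they strictly dominate every other degree;
the GMT generator plants one term equal to a chosen gene set among random
terms; regulator tables plant one regulator whose targets are drawn from
the DEG set until it strictly out-ranks the background. All generators are
pure functions of parameters + seed (byte-identical reruns).

What passing on these data does **not** show: the generator has no probe
level, no batch or platform effects, no intensity-dependent variance, no
correlated genes, and noise is exactly Gaussian — so recovery rates here
are upper bounds on real-cohort behaviour, and the package makes no claim
about reproducing any specific published cohort's DEG counts, which depend
on the cohorts and annotation-library versions used.

## Numerical choices and degenerate inputs

- Constant (zero-variance) rows: excluded and reported at z-scoring and at
  testing; a t-statistic is never fabricated.
- Missing values: rejected at read time with the offending cell named;
  imputation is out of scope.
- BH: statsmodels' step-up implementation; validated in the test suite
  against an independent hand-written step-up oracle.
- Hypergeometric tail: scipy's exact survival function; validated against
  exhaustive Fraction-arithmetic enumeration for all universes ≤ 12.
- Tie-breaking everywhere (rankings, collapsing, sort orders) is
  deterministic: score, then lexicographic symbol; pipeline artifacts embed
  no timestamps, so identical config + inputs ⇒ byte-identical outputs.
- Empty results are warnings, not errors, wherever biology allows them
  (no shared genes, no drug hits, no regulator touching a DEG).

## Problem sizes in the validation scripts

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
exercise every code path with comfortable statistical power: 1000-gene,
10 vs 10 cohorts (50 planted DEGs) over 10–20 seeds for DEG recovery; a
1-target + 4-factor family with pairwise blocks (10/8/6/4) at effect 3.0
for exact diseasome recovery; 50-term libraries over a 1000-gene universe,
50–100 seeded runs for enrichment power and null calibration; 200-node
PPI graphs and 30-regulator tables over 10 seeds for network recovery; and
a 5-condition, 600-gene workspace for the end-to-end determinism check.

## Known limitations

- Symbol-based gene identity ignores aliasing and cross-platform probe
  semantics; supplying curated probe maps is the supported remedy.
- The pooled t-test assumes equal group variances; a Welch option is
  deliberately not offered to keep the contract of the classical analysis.
- Overlap significance between DEG sets is available through the
  hypergeometric machinery but pairwise intersection itself reports raw
  counts, as diseasome figures conventionally do.
- EnrichR-style combined scores, GSEA-style ranked tests, and alternative
  hub centralities (MCC, bottleneck, ...) are out of scope.
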