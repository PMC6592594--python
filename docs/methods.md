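# Methods

## Design and model

The pipeline analyses a matched-pair, two-condition bulk RNA-seq design:
embryos conceived with fresh (FRSH) or frozen-thawed (CRYO) sperm from the
same stallion and mare, collected at days 8, 10 and 12 after ovulation,
two replicates per condition per day (12 samples). Every contrast is a
per-day 2-vs-2 comparison; there is no pooled-across-day test, no
covariate modelling and no dispersion shrinkage — the test is deliberately
the simple permutation procedure described below.

### Quantification

Gene-level counts are converted to TPM
(`rate_g = count_g / length_g(kb)`, `TPM_g = 1e6 · rate_g / Σ rate`) and
RPKM (`1e9 · count_g / (length_g(bp) · library size)`). Effective length is
the annotated transcript length as supplied; no fragment-length
correction is applied. Nonzero TPM columns sum to 1e6 by construction;
all-zero samples yield all-zero columns with a logged warning rather than
an error.

A gene is *expressed* when its RPKM strictly exceeds a floor (default
0.4). The floor's scope is configurable: `any` (exceeds the floor in at
least one sample of the contrast — the default, chosen to maximise power
while excluding globally silent genes), `all`, or `condition-mean`.
Filtering is done on RPKM and testing on TPM; within a sample the two
induce the same gene ranking, so the floor is a pure detection criterion.

### Permutation test

With only two replicates per condition, a per-gene label permutation
admits just C(4,2) = 6 distinct assignments (minimum attainable P of 1/3),
so per-gene significance is impossible without sharing information. The
default mode, `label_within_gene`, therefore reassigns each gene's four
TPM values to pseudo-groups uniformly at random in every round and pools
*all* genes' pseudo-differences into one genome-wide null — each gene's
contribution retains its own scale, and the pooled null provides
resolution 1/(B·G+1). The alternative mode `global_score_shuffle`
(shuffling TPM values across genes within each sample) is retained because
the procedure is also defensible read that way; both are seeded and
reproducible.

P values are two-sided on |difference|, with ties counted as exceedances
and an add-one correction (Phipson–Smyth style), so P is never zero and
P ∈ [1/(N+1), 1]. An exhaustive-enumeration mode exists for small designs
and serves as the oracle the sampled null is validated against.

The pooled null has a known consequence: significance in TPM-difference
units favours highly expressed genes. This is intrinsic to the method and
is the reason the candidate definition conjoins the P threshold with a
fold-change filter (|log2 FC| ≥ 1 by default, pseudocount 0.5 TPM on both
means so condition-absent genes remain finite). Candidate lists are
re-flaggable at 0.05 / 0.01 / 0.001 without recomputing the null;
tightening the threshold can only shrink the lists.

### Enrichment

Over-representation uses the EASE score: the one-sided hypergeometric
upper tail of the 2×2 overlap table with the overlap decremented by one
(floored at zero, so overlaps of 0 or 1 give exactly P = 1). Fold
enrichment is (k/n)/(K/N). The universe is the expressed genes of the
contrast — an explicit, reproducible background, in contrast to a
whole-genome reference of another species. Benjamini–Hochberg adjustment
runs across the tested terms of each category; terms with fewer than two
in-universe members are pruned at load time since they cannot reach
significance.

### Network analysis

Interaction edges carry a combined confidence score in [0, 1] (STRING's
0–1000 integer scale is auto-detected and rescaled on read). Edges at or
above the high-confidence cutoff 0.700 (inclusive, matching the usual
high-confidence convention) are positive interactions. The PPI-enrichment
P value for a query list is a seeded permutation test: the internal edge
count of the query versus `n_draws` equal-size node sets drawn uniformly
from the network (optionally stratified by degree decile), add-one
corrected. The analytic model behind the original web service's
vanishingly small P values is not public; the permutation null is labelled
as such in every report, and its floor is 1/(n_draws+1). Clusters are
connected components of the query-induced subgraph by default (no
clustering algorithm is canonical for this analysis); greedy modularity
communities are available behind a flag.

### Phenotype intersection

Down-regulated candidates are intersected with an ortholog-phenotype
table (gene → model-organism ortholog → pipe-separated phenotype terms),
optionally restricted to a term list such as the embryonic-lethality
vocabulary. One-to-many orthology emits one row per ortholog. The table is
a plain TSV; a real MGI/HomoloGene export with the same three columns can
be dropped in, while the packaged generator fabricates a synthetic one.

## Synthetic-data generator

The generator emulates the study conditions so that every stage is
testable offline:

- **Design**: 3 days × {FRSH, CRYO} × 2 replicates; default 29,196 genes
  (the reported per-embryo transcript count), though tests and the
  acceptance script run at ≤ 2,000 genes for speed.
- **Counts**: negative binomial, `Var = μ + d·μ²` (the standard
  overdispersed RNA-seq model; the choice of count law was otherwise
  open). Gene baselines are log-normal with log2-SD 1.5; gene lengths
  log-uniform in 200–10,000 bp; library sizes log-normal around
  `mean_library_size` (default 5×10⁶ reads) with CV 20%, so TPM
  normalisation is non-trivially exercised.
- **Effects**: planted per annotation set and applied on the CRYO side
  only (`CRYO mean × 2^effect`), matching the CRYO-relative-to-FRSH
  framing of the analysis. Down sets carry negative log2 effects.
- **Planted baselines**: planted genes draw their baselines from a
  boosted (+3 log2), tight (SD 0.5 log2) distribution. This is a
  deliberate modelling choice: the gene programmes the analysis is built
  to detect — oxidative phosphorylation, ribosome, histone clusters — are
  coherent, highly abundant housekeeping sets, and a pooled
  TPM-difference null is sensitive precisely in that regime. Planting
  effects uniformly across the dynamic range would test a scenario the
  method is not claimed to handle (low-expression effects are invisible
  to a pooled absolute-difference statistic; that limitation is inherent
  and documented, not worked around).
- **Annotations**: planted sets verbatim plus decoy sets drawn from null
  genes (decoy size defaults to the mean planted-set size); universe =
  all simulated genes.
- **Network**: within-set pairs connected with high probability and high
  mean confidence (default 0.9), background pairs sparse and low
  confidence (default 0.4), scores Gaussian-jittered and clipped to
  [0, 1].
- **Phenotypes**: planted down genes receive embryonic-lethality terms
  with probability 0.6, others 0.05; 80% of genes have an ortholog.

What the generator does **not** emulate: read-level data (FASTQ),
alignment and multi-mapping, isoform structure, GC or positional bias,
batch effects beyond library size, correlated expression between genes
outside planted modules, and the matched-pair correlation structure
(pairs are labelled but replicates are drawn independently). Passing
tests therefore demonstrate the statistical machinery's correctness and
calibration under the stated generative model, not robustness to every
artefact of real sequencing data.

## Numerical choices

- Permutation rounds default to 10,000; the pooled null is streamed in
  chunks of 250 rounds so genome-scale matrices never materialise the
  full null (the chunked path and the materialised path are both exposed
  and agree).
- Seeds: every stochastic component takes an explicit seed; the pipeline
  derives per-stage seeds from the global seed by fixed small offsets and
  records them in the manifest.
- EASE uses the scipy hypergeometric survival function; the test suite
  validates it against an independent direct tail summation over all
  margins up to N = 40.
- Ties in the permutation null count as exceedances (conservative);
  fold changes use a configurable 0.5 TPM pseudocount; `k−1` in the EASE
  score is floored at 0 rather than erroring.
- Degenerate inputs: empty candidate lists yield empty (not erroneous)
  enrichment tables; queries smaller than 2 yield a PPI report with
  observed 0 and P 1; all-zero samples yield zero columns with warnings.

## Problem sizes

The test suite and acceptance script run at reduced scale, chosen so the
statistical claims are still well-powered: calibration and recovery at
2,000 genes × 10,000 rounds, enrichment recovery across 100 (suite) / 60
(script) seeded replicates of a 400-gene simulation with ≥ 50 competing
terms, network recovery across 50/30 replicates of a 300-node network,
and the exhaustive-oracle comparison on 5 genes × 6 assignments × 10,000
sampled rounds.

## Known limitations

- With 2-vs-2 designs the pooled null shares information across genes;
  per-gene P values are calibrated only marginally (the fraction of genes
  below α matches α under the null), not conditionally per gene.
- The absolute-difference statistic has low power for low-expression
  genes regardless of fold change; the fold filter removes
  high-expression/low-fold artefacts but cannot restore that power.
- Down-regulation is intrinsically harder to detect than up-regulation of
  equal |log2 FC| at a fixed baseline, because the difference magnitude
  is 1 − 2^(−e) versus 2^(e) − 1 times the baseline mean.
- The PPI permutation null draws nodes uniformly by default; for queries
  dominated by hubs, enable the degree-binned null.
- BH control is per annotation category, mirroring per-category
  enrichment charts; no control is applied across categories.
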