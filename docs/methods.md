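# Methods

This note documents the models, defaults and numerical choices behind
`bloodsig`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Study design being emulated

The package targets the classic small-cohort blood microarray design:
two groups (default 8 cases vs 6 controls after quality-control
exclusions), one probe-level log2 intensity matrix (~12,600 probes over
~9,000 genes, several probes per gene), a probe annotation with genomic
loci and pseudogene flags, a gene-set collection, and a curated
protein-interaction background network with a gene→object mapping.
Sample QC is honored as an explicit exclude-list input rather than an
automated algorithm, since exclusion criteria are site-specific.

## Synthetic data generator

`synthetic.SimConfig` defines one simulated study; one integer seed is
fanned out through `numpy.random.SeedSequence.spawn` to three fixed-order
child streams (expression, network, gene sets), so identical configs are
byte-identical on disk and a change in one stage's draw count never
perturbs another.

* **Noise model** — i.i.d. Gaussian on the log2 scale, sd 0.5 by
  default. Microarray fold-change arithmetic assumes additive noise on
  log intensities; 0.5 log2 units is a typical between-array residual
  sd for blood arrays, but it is a free choice — no canonical value
  exists for this design.
* **Baselines** — per-gene baseline log2 intensity drawn U(6, 12)
  (scanner mid-range); replicate probes of a gene share the gene mean
  and carry independent noise, reproducing the multi-probe redundancy
  that probe collapsing exists for.
* **Probes per gene** — categorical {1: 0.7, 2: 0.2, 3: 0.1}; with
  9,000 genes this yields ~12,600 probes.
* **Differential genes** — a fraction `frac_deg` (default 0.011, ≈ 99
  genes) get a case-group mean shift of ±log2(FC) with FC ~ U(1.5, 4.0)
  linear; 95% are down-regulated, matching the strongly
  down-regulation-dominated signature this regime emulates.
* **Genome layout and hot spots** — genes sit on 22 chromosomes in index
  order at fixed 10 kb spacing. Six 30-gene hot-spot intervals on
  distinct chromosomes receive a 35/99 share of the planted DEGs (at
  least three each, the reporting threshold); remaining DEGs scatter
  uniformly outside.
* **Annotation gaps** — 5% of probes (only from non-DEG genes, so the
  planted truth stays resolvable) are flagged pseudogene or stripped of
  their gene symbol; they survive DEG selection and drop at collapsing,
  exercising the trimming contract.
* **Network** — Barabási–Albert preferential attachment (default 5,000
  nodes, 3 edges per new node) gives the heavy-tailed degree
  distribution of curated interactomes; edge directions are random and
  effect signs are drawn {+1: 0.45, −1: 0.45, 0: 0.10}. Genes map
  uniformly onto objects; at least one many-to-one case is forced so
  the gene-family (several genes → one group object) path is always
  exercised. Planted hubs are moderate-degree (10–40) non-DEG-mapped
  nodes whose neighborhoods are rewired until half their neighbors (by
  default) are DEG-mapped objects; degree is preserved so plants do not
  distort the degree distribution. Moderate-degree hubs keep the
  required DEG-neighbor count below the number of available DEG
  objects — demanding more is a configuration error.
* **Gene sets** — 50 terms of 10–50 members; 5 planted enriched terms
  draw 60% of members from the planted DEG set, the rest uniformly.

**What the generator does not emulate:** batch effects, probe-sequence
biases, intensity-dependent variance, correlated co-expression modules
beyond the planted group shift, assortative or modular network
structure, and curated-term overlap hierarchies. Passing recovery tests
therefore show the *pipeline logic* is sound under its own null and
signal models, not that any particular biological dataset would yield
the same counts.

## Signature stage

The coefficient-of-variation filter keeps probes with sd/mean > 0.12
(strict inequality), computed by default on anti-logged linear
intensities; the stored scale is available by flag since conventions
differ between toolchains. The filter is idempotent and
order-preserving.

Two-way clustering defaults to 1 − Pearson distance with centroid
linkage for samples and average linkage for probes. The combination
"Euclidean distance with a 1 − r metric" that array suites print is
self-contradictory; 1 − r is taken as the operative metric (it is the
more specific statement and the common default for sample clustering),
with Euclidean available by flag. Probes are z-scored across samples
before sample clustering by default (flag `standardize`), as array
suites typically standardize rows; ties are broken by lexicographic
item id, which also makes results invariant to input row order. No
automated class assignment is made from the dendrogram — separation is
assessed by cutting into two clusters and comparing to labels with the
adjusted Rand index, since group coloring in the emulated protocol is a
post-hoc visual step.

PCA centers (and by default standardizes) probes, then decomposes the
samples × probes matrix; three components are reported by default with
their variance fractions. A constant matrix yields all-zero fractions
with a warning rather than an error.

## DEG stage

Welch's t-test is used because group sizes and variances are unequal by
design; the emulated protocol does not name its test, and Welch is the
conservative default. p-values are left unadjusted for selection —
BH q-values are computed and reported but deliberately not used for the
cut, matching the printed procedure. The signed FC is computed from
arithmetic means of anti-logged values (the convention of array suites),
inclusive at |FC| = 1.4 and exclusive at p = 0.05; zero-variance probes
with equal means get p = 1.

At this design (14 arrays, ~12,600 probes, unadjusted p < 0.05), most
calls are false: the emulated regime plants ~99 true DEGs yet the
thresholds call ~500 genes, i.e. an empirical false discovery
proportion near 0.8. The pipeline reports this proportion but does not
bound it — the thresholds are the protocol's, not ours. One internal
inconsistency of the emulated study is left as documented: its
down-regulated DEG count is printed as 95 in one place and 91 in
another; nothing in this package depends on either value.

## Enrichment stage

Exact hypergeometric upper tails (no normal or chi-square
approximation), BH within one collection at a time; the universe
defaults to annotated non-pseudogene genes on the array, the
background convention of annotation services. Only over-representation
is tested.

## Interactome stage

"Interaction" counts distinct neighbors on the undirected projection of
the directed signed network — a single background degree R per object
implies direction-agnostic counting; direction and sign are retained
for reporting. An object in the dataset never counts itself among its
own neighbors. Tail probabilities are exact: printed values of order
1e-9 to 1e-16 are far outside normal-approximation accuracy, and the z
score is reported descriptively alongside. Significance is α = 0.05 on
the unadjusted tail p (the reporting convention of the emulated
analysis); BH-adjusted values are attached for reference. R = 0 objects
are flagged "isolated" rather than given infinite z.

Exact discrete tails make the null *conservative*: P(p < α) ≤ α, and
for low-degree objects attainable tail values skip α entirely, so the
empirical null flag rate sits well below 5%. Calibration tests
therefore assert the rate is bounded by α within binomial error rather
than equal to it.

Regulator ranking applies the same statistic to transcription-factor
target sets against the DEG list (A = |targets ∩ DEGs|, R = |targets|,
n = |DEGs|, N = |universe|), ranking by z descending; TFs absent from
the DEG list ("hidden" regulators) are scored like any other.

## Hot-spot stage

"Stretch" is made precise as: any run of consecutive genes delimited by
DEGs at both ends with ≥ 3 DEGs, scored P(X ≥ k) for k DEGs among m
consecutive genes given genome totals (G, D); significant windows
(p ≤ 0.05, no multiplicity correction by default, BH by flag) merge
into maximal hot spots with p = min over members. This is
parameter-free, reproduces the "≥ 3 DEGs, p ≤ 0.05" contract exactly,
and is validated against a label-permutation null (uniform permutation
of DEG labels over gene positions, add-one continuity
(hits + 1)/(B + 1)). Conditioning is genome-wide by default with a
per-chromosome flag, since the original tool's internals are not
public. Gene order uses transcript start of the first-listed probe;
strand is ignored (locus position, not orientation, defines a stretch).

## Problem sizes in tests and the acceptance script

Unit tests run a 400-gene/4-chromosome/400-node configuration; recovery
acceptance runs the full default regime (9,000 genes, 5,000-node
network); null calibration uses 200 replicates of a 300-gene matrix;
permutation agreement uses 100,000 replicates on the 20-gene toy and
2,000 per random configuration. These sizes were chosen so the whole
suite completes in well under a minute while keeping binomial standard
errors small relative to the tolerances asserted.

## Known limitations

* The generator's planted effects are mean shifts with homoscedastic
  noise; power estimates under heavy-tailed or intensity-dependent
  noise will differ.
* Gene→object mapping is exact-symbol, case-sensitive; no alias
  resolution.
* The shortest-path network expansion of curated suites is out of
  scope; only direct-edge pairing of over-connected objects is
  reported.
* Headline counts of any particular patient study (DEG totals, variance
  fractions, hot-spot counts) are data-dependent and are not
  reproduction targets of this package.
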