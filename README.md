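# bloodsig

Case–control blood transcriptome analysis for small microarray cohorts:
an unsupervised disease-state signature, differential-expression calling
with probe-to-gene collapsing, gene-set over-representation, interactome
over-connectivity, and chromosomal hot-spot scanning — plus a
synthetic-data generator with planted truth so that every stage can be
validated without access to patient data.

The package is aimed at transcriptomics analysts who work with
probe-level expression matrices (e.g. Affymetrix-style arrays of
peripheral blood from a handful of cases and controls) and want the
classical signature → DEG → enrichment → network → genome-map chain as
a scriptable, tested library instead of a sequence of GUI tools and web
services.

## The statistics at the core

**Differential expression.** Per probe, a Welch two-sample *t*-test on
log2 intensities; the signed fold change is the linear-scale group-mean
ratio, reported as the ratio when ≥ 1 (up in patients, "UIP") and as
its negated reciprocal when < 1 (down, "DIP"). DEGs satisfy *p* < 0.05
and |FC| ≥ 1.4; replicate probes of a gene collapse to the one with the
largest |FC| (ties: lowest *p*, then probe id), after dropping
unannotated and pseudogene probes.

**Interactome over-connectivity.** Map the *n* DEG genes onto objects of
a background network of *N* objects. An object with *R* distinct
neighbors, *A* of them in the dataset, is scored against the
hypergeometric null:

    E  = nR/N                       (expected dataset neighbors)
    sd = sqrt( n (R/N)(1 − R/N)(N − n)/(N − 1) )
    z  = (A − E)/sd,   Ratio = A/E
    p  = P(X ≥ A)  if z ≥ 0,  else  P(X ≤ A)     (exact tails)

Objects with *p* < α and z > 0 are over-connected. The same statistic
applied to transcription-factor target sets ranks regulators, including
"hidden" ones absent from the DEG list itself.

**Gene-set enrichment.** One-sided hypergeometric upper tail per term
against the array's annotated non-pseudogene universe, with
Benjamini–Hochberg FDR across the collection.

**Hot-spot scan.** Order genes per chromosome by transcript start; every
DEG-delimited run of consecutive genes holding ≥ 3 DEGs is scored with
the hypergeometric upper tail given genome-wide gene and DEG totals;
significant (p ≤ 0.05) windows merge into maximal hot spots. A
label-permutation null validates the analytic p-values.

## Worked example

```python
from bloodsig import SimConfig, simulate_all
from bloodsig.deg import test_differential, select_degs, collapse_probes
from bloodsig.interactome import (ConnectivityStats, map_genes_to_objects,
                                  overconnected_set)

# over-connectivity from published counts: 7 of IRF9's 60 neighbors in a
# 102-object dataset, background 26,494 objects
s = ConnectivityStats.from_counts("IRF9", A=7, n=102, R=60, N=26494)
print(f"E={s.E:.3f}  ratio={s.ratio:.1f}  z={s.z:.1f}  p={s.p:.3g}  {s.direction}")

# a full synthetic study: 8 cases vs 6 controls, ~12,600 probes
cfg = SimConfig(seed=1)
matrix, annotation, network, genesets, truth = simulate_all(cfg)
records = collapse_probes(select_degs(test_differential(matrix)), annotation)
called = {r.gene_symbol for r in records}
print(f"{matrix.n_probes} probes, {len(records)} DEG genes called, "
      f"{len(called & set(truth.deg_genes))}/{len(truth.deg_genes)} planted DEGs recovered")
mapping = map_genes_to_objects(sorted(called), network)
over = overconnected_set(mapping.objects, network).over
print(f"n={len(mapping.objects)} dataset objects, {len(over)} over-connected, "
      f"hubs recovered: {len(truth.hub_objects & {s.object_id for s in over})}"
      f"/{len(truth.hub_objects)}")
```

prints

```
E=0.231  ratio=30.3  z=14.1  p=3.32e-09  over
12530 probes, 496 DEG genes called, 95/99 planted DEGs recovered
n=467 dataset objects, 128 over-connected, hubs recovered: 10/10
```

The first line is the exact over-connectivity statistic for one object:
observed dataset neighbors exceed expectation 30-fold, fourteen standard
deviations above the mean. The synthetic run recovers 95 of 99 planted
differential genes and all ten planted network hubs; the large number of
called genes reflects the unadjusted p < 0.05 / |FC| ≥ 1.4 contract at
14 samples and ~12,600 probes (the per-gene false discovery proportion
is reported by the pipeline — see `docs/methods.md`).

A CLI mirrors the library (`bloodsig simulate`, `signature`, `deg`,
`enrich`, `connect`, `hotspot`, `run-all`, `compare`); `run-all` takes a
YAML config and writes all tables plus a JSON run manifest.

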