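"""Interactome over-connectivity of a gene signature.

A dataset of n network objects (genes mapped onto a background network
of N protein-like objects) is tested object by object: an object with R
distinct neighbors in the background and A of them inside the dataset
is compared against the hypergeometric expectation

    E  = n * R / N
    sd = sqrt(n * (R/N) * (1 - R/N) * (N - n) / (N - 1))
    z  = (A - E) / sd
    p  = P(X >= A) when z >= 0, else P(X <= A)     (exact tails)

with Ratio = A / E the connectivity ratio.  "Interaction" means a
distinct neighbor on the undirected projection of the directed signed
network; direction and sign are kept for reporting only.  Tail
probabilities are computed exactly — printed values far below 1e-6 are
outside normal-approximation accuracy.

The same statistic, applied to a transcription factor's curated target
set against a DEG list, ranks regulators — including "hidden" ones that
are not themselves differentially expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .io_formats import InteractionNetwork

__all__ = ["ConnectivityStats", "TopologySummary", "GeneMapping",
           "map_genes_to_objects", "connectivity_stats", "overconnected_set",
           "overconnected_pairs", "regulator_enrichment", "topology_summary"]

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityStats:
    """Over/under-connectivity of one object against a dataset.

    Fields mirror the reporting convention: A observed dataset
    neighbors, n dataset objects, R background degree, N background
    size, E the hypergeometric mean, ratio A/E, z the standardized
    excess and p the exact tail probability (upper when z >= 0, lower
    when z < 0).  ``direction`` is "over"/"under" at the chosen alpha,
    "none" otherwise, or "isolated" when R = 0 (statistic undefined).
    """

    object_id: str
    A: int
    n: int
    R: int
    N: int
    E: float = field(init=False)
    ratio: float = field(init=False)
    z: float = field(init=False)
    p: float = field(init=False)
    direction: str = field(init=False)
    alpha: float = 0.05
    fdr: float = float("nan")      # BH across a scanned object set

    def __post_init__(self) -> None:
        if not (0 <= self.A <= min(self.n, self.R) if self.R else self.A == 0):
            raise ValidationError(
                f"impossible counts A={self.A}, n={self.n}, R={self.R}")
        if self.N < max(self.n, self.R) or self.n < 1:
            raise ValidationError(
                f"impossible background N={self.N} for n={self.n}, R={self.R}")
        if self.R == 0:
            self.E = 0.0
            self.ratio = float("nan")
            self.z = float("nan")
            self.p = float("nan")
            self.direction = "isolated"
            return
        N, n, R, A = self.N, self.n, self.R, self.A
        self.E = n * R / N
        self.ratio = A / self.E
        pfrac = R / N
        sd = np.sqrt(n * pfrac * (1 - pfrac) * (N - n) / (N - 1))
        self.z = (A - self.E) / sd if sd > 0 else 0.0
        if self.z >= 0:
            self.p = float(hypergeom.sf(A - 1, N, R, n))
        else:
            self.p = float(hypergeom.cdf(A, N, R, n))
        if self.p < self.alpha and self.z > 0:
            self.direction = "over"
        elif self.p < self.alpha and self.z < 0:
            self.direction = "under"
        else:
            self.direction = "none"

    @classmethod
    def from_counts(cls, object_id: str, A: int, n: int, R: int, N: int,
                    alpha: float = 0.05) -> "ConnectivityStats":
        return cls(object_id=object_id, A=A, n=n, R=R, N=N, alpha=alpha)

    def to_record(self) -> dict:
        return {"object": self.object_id, "A": self.A, "n": self.n,
                "R": self.R, "N": self.N, "E": self.E, "ratio": self.ratio,
                "z": self.z, "p": self.p, "direction": self.direction,
                "fdr": self.fdr}


class GeneMapping(NamedTuple):
    objects: set[str]          # distinct dataset objects (n = len(objects))
    unmapped: list[str]        # genes with no network object


def map_genes_to_objects(genes: Iterable[str],
                         network: InteractionNetwork) -> GeneMapping:
    """Map gene symbols onto network objects.

    Several genes may map to one object (curated gene-family group
    nodes), so the dataset object count n may be smaller than the gene
    count.  Unmapped genes are reported.
    """
    objects: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        obj = network.gene_to_object.get(g)
        if obj is None:
            unmapped.append(g)
        else:
            objects.add(obj)
    if unmapped:
        logger.warning("%d gene(s) had no network object", len(unmapped))
    return GeneMapping(objects, sorted(unmapped))


def connectivity_stats(object_id: str, dataset_objects: set[str],
                       network: InteractionNetwork,
                       alpha: float = 0.05) -> ConnectivityStats:
    """Connectivity of one object against the dataset object set.

    Neighbors are the distinct union of in- and out-neighbors with self
    excluded; an object belonging to the dataset never counts itself
    among its own dataset neighbors.
    """
    if object_id not in network.graph:
        raise ValidationError(f"unknown object {object_id!r}")
    if not dataset_objects:
        raise ValidationError("empty dataset object set")
    nbrs = network.neighbors_undirected(object_id)
    A = len(nbrs & dataset_objects - {object_id})
    return ConnectivityStats.from_counts(
        object_id, A=A, n=len(dataset_objects), R=len(nbrs), N=network.N,
        alpha=alpha)


class OverconnectivityResult(NamedTuple):
    over: list[ConnectivityStats]      # sorted by p ascending
    under: list[ConnectivityStats]     # reported separately
    isolated: list[str]


def overconnected_set(dataset_objects: set[str],
                      network: InteractionNetwork,
                      alpha: float = 0.05) -> OverconnectivityResult:
    """Scan every background object for over/under-connectivity.

    Returns significantly over-connected objects sorted by p (ties by
    id), under-connected objects separately, and ids of isolated
    objects.  BH-adjusted values across the scanned set are attached to
    each returned statistic (reported, not used for the alpha call).
    """
    stats: list[ConnectivityStats] = []
    isolated: list[str] = []
    for obj in sorted(network.graph.nodes):
        s = connectivity_stats(obj, dataset_objects, network, alpha=alpha)
        if s.direction == "isolated":
            isolated.append(obj)
        else:
            stats.append(s)
    if stats:
        from statsmodels.stats.multitest import multipletests
        fdr = multipletests([s.p for s in stats], method="fdr_bh")[1]
        for s, f in zip(stats, fdr):
            s.fdr = float(f)
    over = sorted((s for s in stats if s.direction == "over"),
                  key=lambda s: (s.p, s.object_id))
    under = sorted((s for s in stats if s.direction == "under"),
                   key=lambda s: (s.p, s.object_id))
    return OverconnectivityResult(over, under, isolated)


class PairReport(NamedTuple):
    pairs: list[tuple[str, str]]               # unordered, joined by >=1 edge
    counts: list[tuple[str, int]]              # per-object pairings, desc


def overconnected_pairs(over_set: Iterable[str],
                        network: InteractionNetwork) -> PairReport:
    """All unordered pairs of over-connected objects joined by an edge,
    and each object's pairing count (sorted descending, ties by id)."""
    objs = sorted(set(over_set))
    if not objs:
        raise ValidationError("empty over-connected set")
    g = network.graph
    pairs = []
    counts = {o: 0 for o in objs}
    for i, u in enumerate(objs):
        for v in objs[i + 1:]:
            if g.has_edge(u, v) or g.has_edge(v, u):
                pairs.append((u, v))
                counts[u] += 1
                counts[v] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return PairReport(pairs, ranked)


def regulator_enrichment(tf_edges: Mapping[str, Iterable[str]],
                         deg_genes: Iterable[str],
                         network_universe: Iterable[str],
                         alpha: float = 0.05) -> list[ConnectivityStats]:
    """Rank transcription factors by over-connectivity of their target
    sets with the DEG list.

    Every TF in ``tf_edges`` is scored — including "hidden" regulators
    absent from the DEG list — with A = |targets ∩ DEGs|, R = |targets|,
    n = |DEGs ∩ universe| and N = |universe|; the ranking is by z
    descending.  TFs with empty target sets are skipped with a warning.
    """
    universe = set(network_universe)
    degs = set(deg_genes) & universe
    if not degs:
        raise ValidationError("no DEG genes inside the universe")
    out = []
    for tf in sorted(tf_edges):
        targets = set(tf_edges[tf]) & universe
        if not targets:
            logger.warning("TF %s has an empty target set; skipped", tf)
            continue
        A = len(targets & degs)
        out.append(ConnectivityStats.from_counts(
            tf, A=A, n=len(degs), R=len(targets), N=len(universe),
            alpha=alpha))
    out.sort(key=lambda s: (-s.z, s.object_id))
    return out


@dataclass
class TopologySummary:
    """Degree split by endpoint membership plus clustering coefficients.

    ``degrees`` is indexed by dataset object with columns ``in_within``,
    ``in_from_background``, ``out_within``, ``out_to_background``.
    Clustering coefficients are means of the local (undirected)
    clustering coefficient over the dataset-induced subgraph and over
    the whole background.
    """

    degrees: pd.DataFrame
    mean_clustering_dataset: float
    mean_clustering_background: float


def topology_summary(dataset_objects: set[str],
                     network: InteractionNetwork) -> TopologySummary:
    g = network.graph
    rows = {}
    for obj in sorted(dataset_objects & set(g.nodes)):
        preds = set(g.predecessors(obj)) - {obj}
        succs = set(g.successors(obj)) - {obj}
        rows[obj] = {
            "in_within": len(preds & dataset_objects),
            "in_from_background": len(preds - dataset_objects),
            "out_within": len(succs & dataset_objects),
            "out_to_background": len(succs - dataset_objects),
        }
    und = network.undirected()
    sub = und.subgraph(dataset_objects & set(und.nodes))
    cc_data = (nx.average_clustering(sub) if sub.number_of_nodes() else 0.0)
    cc_back = (nx.average_clustering(und) if und.number_of_nodes() else 0.0)
    degrees = pd.DataFrame.from_dict(rows, orient="index")
    return TopologySummary(degrees, float(cc_data), float(cc_back))
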