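"""Synthetic expression, annotation, gene-set and network generator.

Every downstream stage of the pipeline (signature, DEG calling,
enrichment, interactome over-connectivity, hot-spot scan) is testable
against *planted* structure produced here: a two-group peripheral-blood
style matrix (default 8 cases vs 6 controls, ~12,600 probes over 9,000
genes with redundant probes per gene), a minority of mostly
down-regulated differential genes, DEG loci clustered into chromosomal
hot spots, a scale-free signed interaction network with planted
over-connected hubs, and a gene-set collection with planted enriched
terms.  The :class:`TruthRecord` returned alongside each artifact lists
exactly what was planted.

Defaults mirror the emulated study regime: 8 vs 6 samples, linear fold
changes drawn from 1.5-4.0, i.i.d. Gaussian noise of 0.5 on the log2
scale, ~99 differential genes of which ~95% are down-regulated, 6 hot
spots holding roughly a 35/99 share of the DEGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (ExpressionMatrix, GeneSetCollection,
                         InteractionNetwork, ProbeAnnotation)

__all__ = ["SimConfig", "TruthRecord", "simulate_expression",
           "simulate_network", "simulate_genesets", "simulate_all"]

# per-gene baseline log2 intensity is drawn uniformly from this range;
# typical scanner dynamic range for present transcripts
_BASELINE_LOG2 = (6.0, 12.0)
# share of planted DEGs placed inside hot spots (in/out split of the
# emulated study: 35 of 99)
_HOTSPOT_DEG_SHARE = 35 / 99


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    The same seed always yields byte-identical artifacts.  Counts are
    positive, fractions live in [0, 1] and the fold-change range is on
    the linear scale with lower bound > 1.
    """

    n_cases: int = 8
    n_controls: int = 6
    n_genes: int = 9000
    probes_per_gene_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    frac_deg: float = 0.011
    deg_direction_frac_down: float = 0.95
    fc_range: tuple[float, float] = (1.5, 4.0)
    noise_sd: float = 0.5
    n_chromosomes: int = 22
    n_hotspots: int = 6
    hotspot_span_genes: int = 30
    frac_pseudogene: float = 0.05
    network_nodes: int = 5000
    network_attachment: int = 3
    n_hub_plants: int = 10
    hub_neighborhood_deg_frac: float = 0.5
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)
    n_enriched_terms: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "n_genes": self.n_genes, "n_chromosomes": self.n_chromosomes,
            "network_nodes": self.network_nodes,
            "network_attachment": self.network_attachment,
            "n_terms": self.n_terms,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive (got {v})")
        for name in ("frac_deg", "deg_direction_frac_down", "frac_pseudogene",
                     "hub_neighborhood_deg_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1] (got {v})")
        if self.n_hotspots < 0 or self.n_hub_plants < 0 or self.n_enriched_terms < 0:
            raise ConfigurationError("plant counts must be non-negative")
        lo, hi = self.fc_range
        if lo <= 1.0 or hi < lo:
            raise ConfigurationError(
                f"fc_range lower bound must exceed 1 and be ordered (got {self.fc_range})")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        probs = self.probes_per_gene_distribution
        if not probs or any(k < 1 for k in probs) or any(p < 0 for p in probs.values()):
            raise ConfigurationError("probes_per_gene_distribution malformed")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("probes_per_gene_distribution must sum to 1")
        t_lo, t_hi = self.term_size_range
        if t_lo < 1 or t_hi < t_lo:
            raise ConfigurationError("term_size_range malformed")
        if t_hi > self.n_genes:
            raise ConfigurationError(
                f"term size {t_hi} exceeds gene universe {self.n_genes}")
        if self.network_nodes < self.n_hub_plants:
            raise ConfigurationError("network_nodes must be >= n_hub_plants")
        genes_per_chrom = self.n_genes // self.n_chromosomes
        if self.n_hotspots:
            if self.hotspot_span_genes < 3:
                raise ConfigurationError(
                    "hotspot_span_genes must be >= 3 (each hot spot holds "
                    ">= 3 planted DEGs)")
            per_chrom = math.ceil(self.n_hotspots / self.n_chromosomes)
            if self.hotspot_span_genes * per_chrom > genes_per_chrom:
                raise ConfigurationError(
                    "hotspot_span_genes x hot spots per chromosome "
                    f"({self.hotspot_span_genes} x {per_chrom}) exceeds the "
                    f"{genes_per_chrom} genes available per chromosome")
            n_deg = round(self.frac_deg * self.n_genes)
            if 3 * self.n_hotspots > n_deg:
                raise ConfigurationError(
                    f"{self.n_hotspots} hot spots need >=3 planted DEGs each "
                    f"but only {n_deg} DEGs are planted")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["probes_per_gene_distribution"] = {
            str(k): v for k, v in self.probes_per_gene_distribution.items()}
        d["fc_range"] = list(self.fc_range)
        d["term_size_range"] = list(self.term_size_range)
        return d

    # one seed, fanned out to fixed-order independent child streams so
    # that a change in one stage's draw count never perturbs another
    def _child_rngs(self) -> tuple[np.random.Generator, ...]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


@dataclass
class TruthRecord:
    """What was planted: the answer key for recovery tests.

    ``deg_genes`` maps gene symbol -> true signed linear fold change
    (negative = down in cases).  ``hotspot_intervals`` are
    (chromosome, start gene index, end gene index), indices into that
    chromosome's start-ordered gene list, inclusive.  Each interval
    contains at least three planted DEG genes.
    """

    deg_genes: dict[str, float] = field(default_factory=dict)
    hub_objects: set[str] = field(default_factory=set)
    hotspot_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    enriched_terms: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "deg_genes": dict(sorted(self.deg_genes.items())),
            "hub_objects": sorted(self.hub_objects),
            "hotspot_intervals": [list(t) for t in self.hotspot_intervals],
            "enriched_terms": sorted(self.enriched_terms),
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimConfig
                        ) -> tuple[ExpressionMatrix, ProbeAnnotation, TruthRecord]:
    """Simulate the probe-level matrix, its annotation and the truth.

    Genes are laid out on ``n_chromosomes`` chromosomes in index order
    with fixed 10 kb spacing.  Hot-spot intervals of
    ``hotspot_span_genes`` consecutive genes are placed on distinct
    chromosomes (round-robin) and receive a 35/99 share of the planted
    DEGs (at least 3 each); the remaining DEGs scatter outside.  Planted
    DEG genes shift the case-group mean by +/- log2(FC) with FC drawn
    uniformly from ``fc_range``; replicate probes of a gene carry
    independent noise around the same gene mean.  A ``frac_pseudogene``
    share of probes (from non-DEG genes) is flagged pseudogene or left
    unannotated, so they survive to DEG selection but drop at collapsing.
    """
    rng, _, _ = config._child_rngs()
    genes = _gene_ids(config.n_genes)
    genes_per_chrom = config.n_genes // config.n_chromosomes

    # --- genome layout ----------------------------------------------------
    chrom_of: dict[str, str] = {}
    start_of: dict[str, int] = {}
    chrom_genes: dict[str, list[str]] = {}
    gi = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_here = genes_per_chrom + (1 if c < config.n_genes % config.n_chromosomes else 0)
        chrom_genes[chrom] = []
        for j in range(n_here):
            g = genes[gi]
            chrom_of[g] = chrom
            start_of[g] = 1 + j * 10_000
            chrom_genes[chrom].append(g)
            gi += 1

    # --- hot spots and DEG placement -------------------------------------
    n_deg = round(config.frac_deg * config.n_genes)
    hotspot_intervals: list[tuple[str, int, int]] = []
    in_hotspot_genes: list[str] = []
    if config.n_hotspots:
        per_hot = max(3, round(_HOTSPOT_DEG_SHARE * n_deg / config.n_hotspots))
        chrom_cursor: dict[str, int] = {}
        for h in range(config.n_hotspots):
            chrom = f"chr{(h % config.n_chromosomes) + 1}"
            offset = chrom_cursor.get(chrom, 0)
            lo = offset
            hi = lo + config.hotspot_span_genes - 1
            chrom_cursor[chrom] = hi + 1
            hotspot_intervals.append((chrom, lo, hi))
            span = chrom_genes[chrom][lo:hi + 1]
            budget = n_deg - 3 * (config.n_hotspots - h - 1) - len(in_hotspot_genes)
            k_h = min(per_hot, len(span), budget)  # all three are >= 3
            picked = rng.choice(len(span), size=k_h, replace=False)
            in_hotspot_genes.extend(span[i] for i in sorted(picked))
    hot_set = set()
    for chrom, lo, hi in hotspot_intervals:
        hot_set.update(chrom_genes[chrom][lo:hi + 1])
    n_outside = n_deg - len(in_hotspot_genes)
    outside_pool = [g for g in genes if g not in hot_set]
    picked = rng.choice(len(outside_pool), size=n_outside, replace=False)
    deg_genes = in_hotspot_genes + [outside_pool[i] for i in sorted(picked)]

    # --- true fold changes ------------------------------------------------
    lo_fc, hi_fc = config.fc_range
    truth_fc: dict[str, float] = {}
    for g in deg_genes:
        fc = float(rng.uniform(lo_fc, hi_fc))
        down = rng.random() < config.deg_direction_frac_down
        truth_fc[g] = -fc if down else fc

    # --- probes -----------------------------------------------------------
    ks = sorted(config.probes_per_gene_distribution)
    probs = np.array([config.probes_per_gene_distribution[k] for k in ks])
    probes_per_gene = rng.choice(ks, size=config.n_genes, p=probs / probs.sum())
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    counter = 1
    for g, k in zip(genes, probes_per_gene):
        for _ in range(int(k)):
            probe_ids.append(f"{counter}_at")
            probe_gene.append(g)
            counter += 1

    # --- intensities --------------------------------------------------------
    n_samples = config.n_cases + config.n_controls
    samples = ([f"case{i + 1:02d}" for i in range(config.n_cases)]
               + [f"ctrl{i + 1:02d}" for i in range(config.n_controls)])
    group_of = {s: ("case" if s.startswith("case") else "control")
                for s in samples}
    baseline = rng.uniform(*_BASELINE_LOG2, size=config.n_genes)
    base_of = dict(zip(genes, baseline))
    shift_of = {g: math.log2(abs(fc)) * (1 if fc > 0 else -1)
                for g, fc in truth_fc.items()}
    means = np.empty((len(probe_ids), n_samples))
    for i, g in enumerate(probe_gene):
        mu = base_of[g]
        delta = shift_of.get(g, 0.0)
        means[i, :config.n_cases] = mu + delta
        means[i, config.n_cases:] = mu
    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples), group_of)

    # --- annotation (pseudogene / unannotated probes) ---------------------
    deg_set = set(deg_genes)
    eligible = [i for i, g in enumerate(probe_gene) if g not in deg_set]
    n_flag = round(config.frac_pseudogene * len(probe_ids))
    flagged = rng.choice(len(eligible), size=min(n_flag, len(eligible)),
                         replace=False)
    flagged_idx = sorted(eligible[i] for i in flagged)
    pseudo_idx = set(flagged_idx[::2])
    unannot_idx = set(flagged_idx[1::2])
    gene_index = {g: i for i, g in enumerate(genes)}
    rows = []
    for i, (pid, g) in enumerate(zip(probe_ids, probe_gene)):
        symbol = "" if i in unannot_idx else g
        rows.append({
            "gene_symbol": symbol,
            "entrez_id": str(10_000 + gene_index[g]) if symbol else "",
            "chromosome": chrom_of[g],
            "start": start_of[g],
            "end": start_of[g] + 999,
            "strand": "+" if (start_of[g] // 10_000) % 2 == 0 else "-",
            "pseudogene_flag": i in pseudo_idx,
        })
    annotation = ProbeAnnotation(pd.DataFrame(rows, index=pd.Index(probe_ids,
                                                                   name="probe_id")))
    truth = TruthRecord(deg_genes=truth_fc, hotspot_intervals=hotspot_intervals)
    return matrix, annotation, truth


def simulate_network(config: SimConfig, truth: TruthRecord
                     ) -> tuple[InteractionNetwork, TruthRecord]:
    """Scale-free directed signed network with planted over-connected hubs.

    Topology is preferential attachment (Barabasi-Albert) with random
    edge directions and +1/-1/0 effect signs.  Genes map uniformly onto
    objects (many-to-one guaranteed).  Each planted hub is a
    moderate-degree node outside the DEG-mapped object set whose
    neighborhood is rewired so that a ``hub_neighborhood_deg_frac``
    fraction of its neighbors are DEG-mapped objects; hub degree is
    preserved.
    """
    _, rng, _ = config._child_rngs()
    n = config.network_nodes
    width = max(5, len(str(n)))
    obj_ids = [f"OBJ{i:0{width}d}" for i in range(1, n + 1)]
    ba_seed = int(rng.integers(0, 2**31 - 1))
    ug = nx.barabasi_albert_graph(n, config.network_attachment, seed=ba_seed)

    g = nx.DiGraph()
    g.add_nodes_from(obj_ids)
    edges = sorted(ug.edges())
    flips = rng.random(len(edges)) < 0.5
    signs = rng.choice([-1, 0, 1], size=len(edges), p=[0.45, 0.10, 0.45])
    for (u, v), flip, sign in zip(edges, flips, signs):
        if flip:
            u, v = v, u
        g.add_edge(obj_ids[u], obj_ids[v], sign=int(sign))

    # gene -> object mapping; force one many-to-one pair (gene-family case)
    genes = _gene_ids(config.n_genes)
    assign = rng.integers(0, n, size=config.n_genes)
    gene_to_object = {gene: obj_ids[assign[i]] for i, gene in enumerate(genes)}
    if len(set(gene_to_object.values())) == len(gene_to_object) and len(genes) >= 2:
        gene_to_object[genes[1]] = gene_to_object[genes[0]]

    deg_objects = sorted({gene_to_object[g_] for g_ in truth.deg_genes
                          if g_ in gene_to_object})
    hub_objects: set[str] = set()
    if config.n_hub_plants:
        und = g.to_undirected()
        candidates = sorted(o for o in obj_ids
                            if o not in deg_objects and 10 <= und.degree(o) <= 40)
        if len(candidates) < config.n_hub_plants:
            raise ConfigurationError(
                f"only {len(candidates)} hub candidates with degree 10-40")
        picked = rng.choice(len(candidates), size=config.n_hub_plants,
                            replace=False)
        for idx in sorted(picked):
            hub = candidates[idx]
            nbrs = sorted(set(und.neighbors(hub)))
            need = math.ceil(config.hub_neighborhood_deg_frac * len(nbrs))
            pool = [o for o in deg_objects if o != hub and not und.has_edge(hub, o)]
            already = sum(1 for x in nbrs if x in set(deg_objects))
            need_new = max(0, need - already)
            if need_new > len(pool):
                raise ConfigurationError(
                    f"hub {hub} needs {need_new} DEG neighbors but only "
                    f"{len(pool)} DEG objects are available")
            new_nbrs = [pool[i] for i in
                        sorted(rng.choice(len(pool), size=need_new, replace=False))]
            removable = [x for x in nbrs if x not in set(deg_objects)]
            for old, new in zip(removable, new_nbrs):
                for e in ((hub, old), (old, hub)):
                    if g.has_edge(*e):
                        g.remove_edge(*e)
                und.remove_edge(hub, old)
                sign = int(rng.choice([-1, 0, 1], p=[0.45, 0.10, 0.45]))
                if rng.random() < 0.5:
                    g.add_edge(hub, new, sign=sign)
                else:
                    g.add_edge(new, hub, sign=sign)
                und.add_edge(hub, new)
            hub_objects.add(hub)

    network = InteractionNetwork(g, gene_to_object)
    truth.hub_objects = hub_objects
    return network, truth


def simulate_genesets(config: SimConfig, truth: TruthRecord
                      ) -> tuple[GeneSetCollection, TruthRecord]:
    """Gene-set collection with ``n_enriched_terms`` planted terms.

    Enriched terms draw 60% of their members from the planted DEG set,
    the rest uniformly; background terms draw uniformly from the whole
    gene universe.
    """
    _, _, rng = config._child_rngs()
    genes = _gene_ids(config.n_genes)
    deg = sorted(truth.deg_genes)
    lo, hi = config.term_size_range
    if config.n_enriched_terms > config.n_terms:
        raise ConfigurationError("n_enriched_terms exceeds n_terms")
    enriched_pos = set(
        int(i) for i in rng.choice(config.n_terms,
                                   size=config.n_enriched_terms, replace=False))
    terms = []
    enriched_ids: set[str] = set()
    for t in range(config.n_terms):
        term_id = f"T{t + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if t in enriched_pos and deg:
            k_deg = min(math.ceil(0.6 * size), len(deg))
            members = {deg[i] for i in rng.choice(len(deg), size=k_deg,
                                                  replace=False)}
            rest_pool = [g for g in genes if g not in members]
            extra = rng.choice(len(rest_pool), size=size - len(members),
                               replace=False)
            members |= {rest_pool[i] for i in extra}
            enriched_ids.add(term_id)
            desc = "planted enriched term"
        else:
            members = {genes[i] for i in rng.choice(config.n_genes, size=size,
                                                    replace=False)}
            desc = "background term"
        terms.append((term_id, desc, tuple(sorted(members))))
    truth.enriched_terms = enriched_ids
    return GeneSetCollection(terms), truth


def simulate_all(config: SimConfig):
    """Run all three generators in fixed order; returns a 5-tuple
    (matrix, annotation, network, genesets, truth)."""
    matrix, annotation, truth = simulate_expression(config)
    network, truth = simulate_network(config, truth)
    genesets, truth = simulate_genesets(config, truth)
    return matrix, annotation, network, genesets, truth
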