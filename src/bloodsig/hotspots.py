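"""Chromosomal hot-spot scan over genome-ordered genes.

Genes are ordered per chromosome by transcript start (duplicate probes
masked: one locus per gene, first-listed probe).  Candidate windows are
runs of consecutive genes delimited by DEG genes at both ends and
containing at least ``min_k`` DEGs; a window of m genes holding k DEGs
is scored against genome-wide totals (G genes, D DEGs) with the
hypergeometric upper tail p = P(X >= k).  Windows with p <= alpha are
retained and overlapping or adjacent significant windows are merged
into maximal hot spots whose p is the minimum over merged members.  A
label-permutation null validates the analytic p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .io_formats import ProbeAnnotation

__all__ = ["HotspotWindow", "order_genome", "scan_windows",
           "permutation_null", "hotspot_membership"]

logger = logging.getLogger(__name__)


@dataclass
class HotspotWindow:
    chromosome: str
    start_bp: int                 # 1-based inclusive
    end_bp: int
    member_genes: list[str]       # ordered by start
    m: int                        # genes in window
    k: int                        # DEGs in window
    p_value: float
    source: str = "analytic"
    # gene-index interval on the chromosome's ordered list (inclusive)
    start_index: int = 0
    end_index: int = 0

    def to_record(self) -> dict:
        return {"chromosome": self.chromosome, "start_bp": self.start_bp,
                "end_bp": self.end_bp, "m": self.m, "k": self.k,
                "p_value": self.p_value, "source": self.source,
                "genes": ",".join(self.member_genes)}


def order_genome(annotation: ProbeAnnotation) -> dict[str, pd.DataFrame]:
    """Per-chromosome start-ordered unique gene table.

    Each gene appears once, located at its first-listed probe's locus;
    a gene annotated on two chromosomes keeps the first and triggers a
    warning.  Returns chromosome -> DataFrame(gene, start, end) sorted
    by start (ties by gene symbol); empty chromosomes are absent.
    """
    t = annotation.table
    usable = t[(t["gene_symbol"] != "") & t["start"].notna()
               & (t["chromosome"].fillna("") != "")]
    seen: dict[str, tuple[str, int, int]] = {}
    for probe_id, row in usable.iterrows():
        gene = str(row["gene_symbol"])
        if gene in seen:
            if seen[gene][0] != str(row["chromosome"]):
                warnings.warn(
                    f"gene {gene} annotated on {seen[gene][0]} and "
                    f"{row['chromosome']}; keeping first")
            continue
        seen[gene] = (str(row["chromosome"]), int(row["start"]), int(row["end"]))
    by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for gene, (chrom, start, end) in seen.items():
        by_chrom.setdefault(chrom, []).append((gene, start, end))
    ordered = {}
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom], key=lambda r: (r[1], r[0]))
        ordered[chrom] = pd.DataFrame(rows, columns=["gene", "start", "end"])
    return ordered


def _flags_by_chrom(ordered_genes: Mapping[str, pd.DataFrame],
                    deg_flags: Mapping[str, Sequence[bool]] | Iterable[str]
                    ) -> dict[str, np.ndarray]:
    """Accept either per-chromosome boolean arrays aligned to the gene
    order or a plain collection of DEG gene symbols."""
    if isinstance(deg_flags, Mapping):
        out = {}
        for chrom, df in ordered_genes.items():
            flags = np.asarray(deg_flags[chrom], dtype=bool)
            if len(flags) != len(df):
                raise ValidationError(
                    f"deg_flags for {chrom} has length {len(flags)}, "
                    f"expected {len(df)}")
            out[chrom] = flags
        return out
    deg_set = set(deg_flags)
    return {chrom: df["gene"].isin(deg_set).to_numpy()
            for chrom, df in ordered_genes.items()}


def scan_windows(ordered_genes: Mapping[str, pd.DataFrame],
                 deg_flags, min_k: int = 3, alpha: float = 0.05,
                 per_chromosome_totals: bool = False,
                 bh_adjust: bool = False) -> list[HotspotWindow]:
    """Scan all DEG-delimited windows; return merged significant hot spots.

    ``deg_flags`` is either a set of DEG gene symbols or a mapping
    chromosome -> boolean array aligned to the ordered gene list.  The
    null conditions on genome-wide totals by default
    (``per_chromosome_totals`` switches to within-chromosome totals).
    With ``bh_adjust`` the candidate windows' p-values are BH-adjusted
    before the alpha cut (off by default).
    """
    if min_k < 1:
        raise ValidationError("min_k must be >= 1")
    flags = _flags_by_chrom(ordered_genes, deg_flags)
    G_all = sum(len(df) for df in ordered_genes.values())
    D_all = int(sum(f.sum() for f in flags.values()))
    if D_all == 0:
        return []

    candidates: list[tuple[str, int, int, int, int, float]] = []
    for chrom, df in ordered_genes.items():
        f = flags[chrom]
        pos = np.flatnonzero(f)
        if len(pos) < min_k:
            continue
        G = len(df) if per_chromosome_totals else G_all
        D = int(f.sum()) if per_chromosome_totals else D_all
        for a in range(len(pos)):
            for b in range(a + min_k - 1, len(pos)):
                lo, hi = int(pos[a]), int(pos[b])
                m = hi - lo + 1
                k = b - a + 1
                p = float(hypergeom.sf(k - 1, G, D, m))
                candidates.append((chrom, lo, hi, m, k, p))
    if bh_adjust and candidates:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([c[5] for c in candidates], method="fdr_bh")[1]
        candidates = [(*c[:5], float(q)) for c, q in zip(candidates, adj)]
    significant = [c for c in candidates if c[5] <= alpha]

    # merge overlapping/adjacent significant windows per chromosome
    hotspots: list[HotspotWindow] = []
    for chrom in sorted({c[0] for c in significant}):
        wins = sorted((c for c in significant if c[0] == chrom),
                      key=lambda c: (c[1], c[2]))
        merged: list[list] = []
        for _, lo, hi, _m, _k, p in wins:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2] = min(merged[-1][2], p)
            else:
                merged.append([lo, hi, p])
        df = ordered_genes[chrom]
        f = flags[chrom]
        for lo, hi, p in merged:
            genes = list(df["gene"].iloc[lo:hi + 1])
            hotspots.append(HotspotWindow(
                chromosome=chrom,
                start_bp=int(df["start"].iloc[lo]),
                end_bp=int(df["end"].iloc[hi]),
                member_genes=genes,
                m=hi - lo + 1,
                k=int(f[lo:hi + 1].sum()),
                p_value=p,
                start_index=lo,
                end_index=hi,
            ))
    hotspots.sort(key=lambda h: (h.chromosome, h.start_bp))
    return hotspots


def permutation_null(ordered_genes: Mapping[str, pd.DataFrame], deg_flags,
                     window: HotspotWindow, B: int = 10_000,
                     seed: int | None = None) -> float:
    """Empirical scan p for one window by permuting DEG labels.

    DEG labels are shuffled uniformly over all genome positions B times;
    the empirical p is the fraction of permutations placing >= k DEGs
    into the window's m-gene span, with add-one continuity
    (count + 1) / (B + 1).
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    flags = _flags_by_chrom(ordered_genes, deg_flags)
    chroms = sorted(ordered_genes)
    G = sum(len(ordered_genes[c]) for c in chroms)
    D = int(sum(flags[c].sum() for c in chroms))
    # the window's span as absolute positions in the genome-wide order
    offset = 0
    span = None
    for c in chroms:
        if c == window.chromosome:
            span = (offset + window.start_index, offset + window.end_index)
            break
        offset += len(ordered_genes[c])
    if span is None:
        raise ValidationError(f"window chromosome {window.chromosome!r} unknown")
    lo, hi = span
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(B, 64_000_000 // max(G, 1) // 8))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, G))
        # positions of the D smallest keys per row = a uniform draw of D
        # DEG positions without replacement
        part = np.argpartition(keys, D - 1, axis=1)[:, :D]
        inside = ((part >= lo) & (part <= hi)).sum(axis=1)
        hits += int((inside >= window.k).sum())
        done += b
    return (hits + 1) / (B + 1)


class MembershipReport:
    """DEG membership per hot spot plus the outside complement."""

    def __init__(self, inside: dict[str, list[str]], outside: list[str]):
        self.inside = inside          # hotspot label -> DEG genes inside
        self.outside = outside        # DEGs in no hot spot

    @property
    def n_inside(self) -> int:
        return sum(len(v) for v in self.inside.values())

    @property
    def n_outside(self) -> int:
        return len(self.outside)


def hotspot_membership(hotspots: Sequence[HotspotWindow],
                       deg_records) -> MembershipReport:
    """Split DEGs into in-hot-spot lists and the outside complement.

    ``deg_records`` may be DEGRecord objects or plain gene symbols.
    """
    genes = [getattr(r, "gene_symbol", r) for r in deg_records]
    inside: dict[str, list[str]] = {}
    assigned: set[str] = set()
    for i, hs in enumerate(hotspots, start=1):
        label = f"{hs.chromosome}:{hs.start_bp}-{hs.end_bp}"
        members = [g for g in genes if g in set(hs.member_genes)
                   and g not in assigned]
        inside[label] = members
        assigned.update(members)
    outside = [g for g in genes if g not in assigned]
    return MembershipReport(inside, outside)
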