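"""In-memory containers and readers/writers for every external format.

All tabular formats are plain text (TSV/CSV), gene sets are GMT, genomic
intervals are written as BED (0-based half-open), networks are edge-list
TSV plus a gene-to-object mapping TSV.  Readers validate strictly and
raise :class:`~bloodsig.errors.FormatError` naming the offending line or
cell instead of silently coercing; writers round-trip losslessly.

Annotation coordinates are 1-based inclusive (GFF-like) in memory and on
disk; conversion to BED's 0-based half-open convention happens only in
:func:`write_hotspots_bed`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe-level log2 intensities with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame of shape (probes, samples), log2 intensity units,
        indexed by probe id with sample ids as columns.
    group_of
        Mapping sample id -> ``"case"`` or ``"control"``; must cover
        every sample column.
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing}")
        bad = {s: g for s, g in self.group_of.items()
               if s in cols and g not in GROUPS}
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at probe {idx[r]!r}, sample {cols[c]!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def linear(self) -> pd.DataFrame:
        """Anti-logged (linear-scale) intensities."""
        return 2.0 ** self.values

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids)],
                                dict(self.group_of))

    def drop_samples(self, exclude: Iterable[str]) -> "ExpressionMatrix":
        """Remove samples (e.g. a QC exclusion list)."""
        keep = [s for s in self.values.columns if s not in set(exclude)]
        return ExpressionMatrix(self.values[keep], dict(self.group_of))


@dataclass
class ProbeAnnotation:
    """Probe -> gene/locus table.

    The underlying frame is indexed by probe id with columns
    ``gene_symbol`` (empty string when unannotated), ``entrez_id``,
    ``chromosome``, ``start``, ``end`` (1-based inclusive bp), ``strand``
    and boolean ``pseudogene_flag``.
    """

    table: pd.DataFrame

    COLUMNS = ["gene_symbol", "entrez_id", "chromosome",
               "start", "end", "strand", "pseudogene_flag"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r} in annotation")
        has_coord = self.table["start"].notna() & self.table["end"].notna()
        bad = self.table.loc[has_coord & (self.table["start"] > self.table["end"])]
        if len(bad):
            raise ValidationError(
                f"start > end for probe {bad.index[0]!r}")
        no_chrom = has_coord & (self.table["chromosome"].fillna("") == "")
        if no_chrom.any():
            raise ValidationError(
                "probe with coordinates but empty chromosome: "
                f"{self.table.index[no_chrom][0]!r}")

    def __len__(self) -> int:
        return len(self.table)

    def gene_of(self, probe_id: str) -> str:
        return str(self.table.at[probe_id, "gene_symbol"])

    def annotated(self) -> pd.DataFrame:
        """Rows with a gene symbol and no pseudogene flag."""
        t = self.table
        return t[(t["gene_symbol"] != "") & (~t["pseudogene_flag"])]

    def gene_universe(self) -> set[str]:
        """Annotated, non-pseudogene gene symbols on the array."""
        return set(self.annotated()["gene_symbol"])


@dataclass
class GeneSetCollection:
    """An ordered collection of (term_id, description, members) triples."""

    terms: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for term_id, _desc, members in self.terms:
            if term_id in seen:
                raise ValidationError(f"duplicate term id {term_id!r}")
            seen.add(term_id)
            if len(members) == 0:
                raise ValidationError(f"term {term_id!r} has no members")
            if len(set(members)) != len(members):
                raise ValidationError(f"term {term_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def members(self, term_id: str) -> tuple[str, ...]:
        for tid, _d, m in self.terms:
            if tid == term_id:
                return m
        raise KeyError(term_id)


@dataclass
class InteractionNetwork:
    """Directed signed interaction network over protein-like objects.

    ``graph`` is a :class:`networkx.DiGraph` whose edges carry a ``sign``
    attribute in {+1, -1, 0}.  ``gene_to_object`` maps gene symbols onto
    network objects; several genes may share one object (gene families
    curated as a single group node).  ``N`` — the background size against
    which connectivity is normalized — is the number of objects.
    """

    graph: "nx.DiGraph"
    gene_to_object: dict[str, str]

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            logger.warning("dropping %d self-loop edge(s)", len(loops))
            self.graph.remove_edges_from(loops)
        unknown = {o for o in self.gene_to_object.values()
                   if o not in self.graph}
        if unknown:
            raise ValidationError(
                f"gene_to_object references unknown objects: {sorted(unknown)[:5]}")

    @property
    def N(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def objects(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors_undirected(self, obj: str) -> set[str]:
        """Distinct neighbors on the undirected projection, self excluded."""
        g = self.graph
        nbrs = set(g.successors(obj)) | set(g.predecessors(obj))
        nbrs.discard(obj)
        return nbrs

    def undirected(self) -> "nx.Graph":
        return self.graph.to_undirected(as_view=False)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression(path, sample_sheet_path) -> ExpressionMatrix:
    """Read a probes x samples log2-intensity TSV plus a sample sheet CSV.

    The TSV's first column holds probe ids; the header row holds sample
    ids.  The sample sheet is ``sample,group`` with group in
    {case, control}.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric cell in column {col!r}, row {bad.index[0]!r}")
    sheet = pd.read_csv(sample_sheet_path)
    if not {"sample", "group"} <= set(sheet.columns):
        raise FormatError("sample sheet must have 'sample' and 'group' columns")
    group_of = dict(zip(sheet["sample"].astype(str), sheet["group"].astype(str)))
    logger.info("read expression matrix: %d probes x %d samples",
                df.shape[0], df.shape[1])
    return ExpressionMatrix(df, group_of)


def write_expression(matrix: ExpressionMatrix, path, sample_sheet_path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")
    sheet = pd.DataFrame({
        "sample": matrix.sample_ids,
        "group": [matrix.group_of[s] for s in matrix.sample_ids],
    })
    sheet.to_csv(sample_sheet_path, index=False)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="probe_id",
                     dtype={"gene_symbol": str, "entrez_id": str,
                            "chromosome": str, "strand": str},
                     keep_default_na=False)
    for col in ("start", "end"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["pseudogene_flag"] = df["pseudogene_flag"].astype(str).str.lower().isin(
        ("true", "1", "yes"))
    return ProbeAnnotation(df)


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read tab-separated GMT: term, description, member genes."""
    terms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            term_id, desc, members = parts[0], parts[1], tuple(parts[2:])
            if any(m == "" for m in members):
                raise FormatError(f"{path}:{lineno}: empty member field")
            terms.append((term_id, desc, members))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id, desc, members in collection:
            fh.write("\t".join([term_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def read_network(edges_path, mapping_path) -> InteractionNetwork:
    """Read edge-list TSV (source, target, direction, sign) and a gene
    mapping TSV (gene, object).

    ``direction`` is always ``->`` in the file (edges are stored
    directed); ``sign`` is one of +1/-1/0.  Self-loops are dropped with a
    warning.  Isolated objects may be declared with a ``target`` of ``-``.
    """
    g = nx.DiGraph()
    with open(edges_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["source", "target"]:
            raise FormatError(f"{edges_path}:1: expected source/target header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{edges_path}:{lineno}: expected 4 fields")
            src, dst, _direction, sign = parts
            if dst == "-":           # isolated node declaration
                g.add_node(src)
                continue
            try:
                sign_i = int(sign)
            except ValueError as exc:
                raise FormatError(f"{edges_path}:{lineno}: bad sign {sign!r}") from exc
            if sign_i not in (-1, 0, 1):
                raise FormatError(f"{edges_path}:{lineno}: sign must be -1/0/+1")
            g.add_edge(src, dst, sign=sign_i)
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    if not {"gene", "object"} <= set(mapping.columns):
        raise FormatError("mapping file must have 'gene' and 'object' columns")
    gene_to_object = dict(zip(mapping["gene"], mapping["object"]))
    return InteractionNetwork(g, gene_to_object)


def write_network(network: InteractionNetwork, edges_path, mapping_path) -> None:
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\tdirection\tsign\n")
        written = set()
        for u, v, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t->\t{data.get('sign', 0):+d}\n")
            written.add(u)
            written.add(v)
        for node in sorted(set(network.graph.nodes) - written):
            fh.write(f"{node}\t-\t->\t+0\n")
    with open(mapping_path, "w") as fh:
        fh.write("gene\tobject\n")
        for gene, obj in sorted(network.gene_to_object.items()):
            fh.write(f"{gene}\t{obj}\n")


# ---------------------------------------------------------------------------
# tables, BED, JSON
# ---------------------------------------------------------------------------

def write_table(records: Iterable[Mapping], path) -> None:
    """Write an iterable of record mappings as a TSV with a header row."""
    df = pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def write_hotspots_bed(hotspots, path) -> None:
    """Emit hot spots as BED (0-based half-open): start = 1-based start - 1."""
    with open(path, "w") as fh:
        for i, hs in enumerate(hotspots, start=1):
            fh.write(f"{hs.chromosome}\t{hs.start_bp - 1}\t{hs.end_bp}\t"
                     f"hotspot_{i}\t{hs.k}\t.\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
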