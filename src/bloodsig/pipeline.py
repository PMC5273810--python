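"""End-to-end orchestration: signature -> DEG -> enrichment ->
interactome -> hot spots, with a JSON run manifest.

Every threshold is a named parameter with the protocol's printed
default: CV > 0.12, DEG p < 0.05 and |FC| >= 1.4, hot spots with >= 3
DEGs at p <= 0.05, connectivity and enrichment alpha 0.05.  Sample QC
exclusion is an explicit exclude-list (no automated QC).  A fixed seed
makes the whole run, including any simulated inputs, deterministic.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml

from . import __version__
from . import deg as deg_mod
from . import enrichment as enrich_mod
from . import hotspots as hotspot_mod
from . import interactome as inter_mod
from . import io_formats as io
from . import signature as sig_mod
from .errors import PipelineError, ValidationError

__all__ = ["PipelineConfig", "run_all", "compare_gene_lists", "OverlapReport"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run."""

    expression_path: str
    sample_sheet_path: str
    annotation_path: str
    output_dir: str
    gmt_path: str | None = None
    network_edges_path: str | None = None
    network_mapping_path: str | None = None
    exclude_samples: list[str] = field(default_factory=list)
    cv_threshold: float = 0.12
    deg_p_max: float = 0.05
    deg_fc_min: float = 1.4
    enrichment_alpha: float = 0.05
    connectivity_alpha: float = 0.05
    hotspot_min_k: int = 3
    hotspot_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_threshold",):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("deg_p_max", "deg_fc_min", "enrichment_alpha",
                     "connectivity_alpha", "hotspot_alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.hotspot_min_k < 1:
            raise ValidationError("hotspot_min_k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name: str):
    """Decorate a stage body so failures abort naming the stage."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            except FileNotFoundError as exc:
                raise PipelineError(
                    f"stage {name!r} failed: missing file {exc.filename}") from exc
        return inner
    return wrap


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages and write tables plus a run manifest.

    Returns the manifest: parameters, package version, seed and
    per-stage record counts.  Stages degrade gracefully on empty
    intermediate results (warnings, empty outputs) rather than failing.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }

    # --- load -------------------------------------------------------------
    matrix = _stage("load")(io.read_expression)(
        config.expression_path, config.sample_sheet_path)
    annotation = _stage("load")(io.read_annotation)(config.annotation_path)
    if config.exclude_samples:
        logger.info("excluding %d sample(s) per QC list",
                    len(config.exclude_samples))
        matrix = matrix.drop_samples(config.exclude_samples)
    manifest["stages"]["load"] = {
        "probes": matrix.n_probes, "samples": matrix.n_samples}

    # --- signature ----------------------------------------------------------
    @_stage("signature")
    def _signature():
        filtered = sig_mod.cv_filter(matrix, threshold=config.cv_threshold)
        result = {"cv_filtered_probes": filtered.n_probes}
        if filtered.n_probes >= 2 and matrix.n_samples >= 2:
            samples_tree = sig_mod.hierarchical_cluster(filtered, "samples")
            probes_tree = sig_mod.hierarchical_cluster(filtered, "probes")
            io.write_json({"samples": samples_tree.to_dict(),
                           "probes": probes_tree.to_dict()},
                          out / "cluster_trees.json")
        p = sig_mod.pca(matrix)
        p.component_scores.to_csv(out / "pca_scores.tsv", sep="\t",
                                  index_label="sample")
        result["pca_variance_fraction"] = [float(v) for v in p.variance_fraction]
        return result

    manifest["stages"]["signature"] = _signature()

    # --- DEG ----------------------------------------------------------------
    @_stage("deg")
    def _deg():
        stats = deg_mod.test_differential(matrix)
        selected = deg_mod.select_degs(stats, p_max=config.deg_p_max,
                                       fc_min=config.deg_fc_min)
        records = deg_mod.collapse_probes(selected, annotation)
        io.write_table(
            ({"gene": r.gene_symbol, "probe": r.representative_probe,
              "signed_fc": r.signed_fc, "p_value": r.p_value,
              "direction": r.direction} for r in records),
            out / "deg_table.tsv")
        if not records:
            logger.warning("no DEGs at p<%g, |FC|>=%g",
                           config.deg_p_max, config.deg_fc_min)
        return records, {"probes_tested": len(stats),
                         "probes_selected": len(selected),
                         "genes": len(records)}

    deg_records, deg_counts = _deg()
    manifest["stages"]["deg"] = deg_counts
    deg_genes = [r.gene_symbol for r in deg_records]

    # --- enrichment ---------------------------------------------------------
    if config.gmt_path:
        @_stage("enrichment")
        def _enrich():
            collection = io.read_gmt(config.gmt_path)
            universe = annotation.gene_universe()
            if not deg_genes:
                logger.warning("skipping enrichment: empty DEG list")
                io.write_table([], out / "enrichment.tsv")
                return {"terms_tested": 0, "significant": 0}
            results = enrich_mod.enrich(deg_genes, collection, universe)
            io.write_table(
                ({"term": r.term_id, "k": r.overlap_count, "K": r.term_size,
                  "n": r.query_size, "G": r.universe_size, "p": r.p_value,
                  "fdr": r.fdr, "neg_log10_p": r.neg_log10_p}
                 for r in results),
                out / "enrichment.tsv")
            sig = sum(r.fdr < config.enrichment_alpha for r in results)
            return {"terms_tested": len(results), "significant": sig}

        manifest["stages"]["enrichment"] = _enrich()

    # --- interactome --------------------------------------------------------
    if config.network_edges_path:
        @_stage("interactome")
        def _interactome():
            network = io.read_network(config.network_edges_path,
                                      config.network_mapping_path)
            if not deg_genes:
                logger.warning("skipping interactome: empty DEG list")
                io.write_table([], out / "connectivity.tsv")
                return {"dataset_objects": 0, "over_connected": 0}
            mapping = inter_mod.map_genes_to_objects(deg_genes, network)
            result = inter_mod.overconnected_set(
                mapping.objects, network, alpha=config.connectivity_alpha)
            io.write_table((s.to_record() for s in result.over),
                           out / "connectivity.tsv")
            if result.over:
                report = inter_mod.overconnected_pairs(
                    [s.object_id for s in result.over], network)
                io.write_table(
                    ({"object": o, "pairings": c} for o, c in report.counts),
                    out / "overconnected_pairs.tsv")
            topo = inter_mod.topology_summary(mapping.objects, network)
            io.write_json(
                {"mean_clustering_dataset": topo.mean_clustering_dataset,
                 "mean_clustering_background": topo.mean_clustering_background},
                out / "topology.json")
            return {"dataset_objects": len(mapping.objects),
                    "unmapped_genes": len(mapping.unmapped),
                    "over_connected": len(result.over),
                    "under_connected": len(result.under)}

        manifest["stages"]["interactome"] = _interactome()

    # --- hot spots ------------------------------------------------------------
    @_stage("hotspot")
    def _hotspot():
        ordered = hotspot_mod.order_genome(annotation)
        spots = hotspot_mod.scan_windows(
            ordered, set(deg_genes), min_k=config.hotspot_min_k,
            alpha=config.hotspot_alpha)
        io.write_hotspots_bed(spots, out / "hotspots.bed")
        io.write_table((h.to_record() for h in spots), out / "hotspots.tsv")
        membership = hotspot_mod.hotspot_membership(spots, deg_records)
        return {"hot_spots": len(spots),
                "degs_inside": membership.n_inside,
                "degs_outside": membership.n_outside}

    manifest["stages"]["hotspot"] = _hotspot()

    io.write_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %s", manifest["stages"])
    return manifest


class OverlapReport(NamedTuple):
    intersection: list[str]
    concordant: list[str]          # same direction in both lists
    discordant: list[str]
    concordance: float             # |concordant| / |intersection with dirs|


def compare_gene_lists(deg_genes, reference_list) -> OverlapReport:
    """Intersect a DEG list with a literature gene list.

    Both arguments are either plain symbol iterables or mappings
    symbol -> direction (+1 up / -1 down, or "UIP"/"DIP"/"up"/"down").
    Direction concordance is reported when both sides carry directions.
    """
    def norm(x) -> dict[str, int | None]:
        if isinstance(x, Mapping):
            conv = {"UIP": 1, "DIP": -1, "up": 1, "down": -1, 1: 1, -1: -1}
            out = {}
            for gene, d in x.items():
                if isinstance(d, (int, float)) and d not in (1, -1):
                    d = 1 if d > 0 else -1
                out[str(gene)] = conv.get(d, None)
            return out
        return {str(g): None for g in x}

    a, b = norm(deg_genes), norm(reference_list)
    inter = sorted(set(a) & set(b))
    concordant, discordant = [], []
    for g in inter:
        if a[g] is not None and b[g] is not None:
            (concordant if a[g] == b[g] else discordant).append(g)
    judged = len(concordant) + len(discordant)
    concordance = len(concordant) / judged if judged else float("nan")
    return OverlapReport(inter, concordant, discordant, concordance)
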