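import numpy as np
import pandas as pd
import pytest

from bloodsig.io_formats import ExpressionMatrix, ProbeAnnotation
from bloodsig.synthetic import SimConfig, simulate_all


def make_matrix(values, probes=None, samples=None, n_cases=None):
    """Small ExpressionMatrix from a 2-D array of log2 values."""
    values = np.asarray(values, dtype=float)
    n_p, n_s = values.shape
    probes = probes or [f"p{i}" for i in range(n_p)]
    samples = samples or [f"s{i}" for i in range(n_s)]
    n_cases = n_s // 2 if n_cases is None else n_cases
    groups = {s: ("case" if i < n_cases else "control")
              for i, s in enumerate(samples)}
    return ExpressionMatrix(pd.DataFrame(values, index=probes,
                                         columns=samples), groups)


def make_annotation(rows):
    """Annotation from dicts; fills defaults for untouched columns."""
    full = []
    index = []
    for r in rows:
        r = dict(r)
        index.append(r.pop("probe_id"))
        full.append({
            "gene_symbol": r.get("gene_symbol", ""),
            "entrez_id": r.get("entrez_id", ""),
            "chromosome": r.get("chromosome", "chr1"),
            "start": r.get("start", 1),
            "end": r.get("end", 1000),
            "strand": r.get("strand", "+"),
            "pseudogene_flag": r.get("pseudogene_flag", False),
        })
    return ProbeAnnotation(pd.DataFrame(full, index=pd.Index(index,
                                                             name="probe_id")))


def small_config(**overrides) -> SimConfig:
    """Fast simulation regime for unit tests: 400 genes, 4 chromosomes,
    2 hot spots, a 400-node network with 3 planted hubs."""
    params = dict(
        n_genes=400, n_chromosomes=4, n_hotspots=2, hotspot_span_genes=20,
        frac_deg=0.06, network_nodes=400, network_attachment=2,
        n_hub_plants=3, n_terms=20, term_size_range=(5, 15),
        n_enriched_terms=3, seed=0,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def small_bundle():
    """One shared small simulated study (matrix, annotation, network,
    gene sets, truth)."""
    return simulate_all(small_config(seed=42))
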