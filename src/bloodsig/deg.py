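"""Case-control differential expression with probe-to-gene collapsing.

Per probe, a Welch two-sample t-test on log2 intensities gives the
p-value; the signed fold change is the ratio of linear-scale group
means, reported as the ratio when >= 1 ("UIP", up in patients) and as
its negated reciprocal when < 1 ("DIP", down in patients), so
|signed FC| >= 1 always.  Selection keeps probes with p < 0.05 and
|signed FC| >= 1.4 (FC inclusive, p exclusive); p-values are unadjusted
at this step — BH q-values are computed and reported alongside but do
not drive the cut.  Collapsing drops unannotated and pseudogene probes
and keeps, per gene, the probe with the largest |signed FC|, breaking
ties by lowest p then lexicographic probe id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import ExpressionMatrix, ProbeAnnotation

__all__ = ["DifferentialStats", "DEGRecord", "test_differential",
           "select_degs", "collapse_probes", "signed_fold_change"]


@dataclass
class DifferentialStats:
    probe_id: str
    mean_case: float          # linear scale
    mean_control: float       # linear scale
    signed_fc: float          # |signed_fc| >= 1; sign tracks case - control
    t_stat: float
    p_value: float
    q_value: float = float("nan")   # BH across all tested probes (reported only)


@dataclass
class DEGRecord:
    gene_symbol: str
    representative_probe: str
    signed_fc: float
    p_value: float
    direction: str            # "UIP" (up in patients) or "DIP" (down)


def signed_fold_change(mean_case: float, mean_control: float) -> float:
    """Linear-mean ratio with the +/- reporting convention.

    Equal means give +1.0 by convention.
    """
    ratio = mean_case / mean_control
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def test_differential(matrix: ExpressionMatrix) -> list[DifferentialStats]:
    """Per-probe Welch t-test (log2 scale) and signed linear fold change."""
    cases = matrix.samples_in_group("case")
    controls = matrix.samples_in_group("control")
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {len(cases)} cases, "
            f"{len(controls)} controls)")
    log_case = matrix.values[cases].to_numpy(dtype=float)
    log_ctrl = matrix.values[controls].to_numpy(dtype=float)
    t, p = _st.ttest_ind(log_case, log_ctrl, axis=1, equal_var=False)
    # zero variance in both groups with equal means: no evidence, p = 1
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    mean_case = (2.0 ** log_case).mean(axis=1)
    mean_ctrl = (2.0 ** log_ctrl).mean(axis=1)
    out = []
    for i, probe in enumerate(matrix.probe_ids):
        out.append(DifferentialStats(
            probe_id=probe,
            mean_case=float(mean_case[i]),
            mean_control=float(mean_ctrl[i]),
            signed_fc=signed_fold_change(mean_case[i], mean_ctrl[i]),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
        ))
    return out


def select_degs(stats: list[DifferentialStats], p_max: float = 0.05,
                fc_min: float = 1.4) -> list[DifferentialStats]:
    """Keep probes with p < p_max and |signed FC| >= fc_min."""
    if p_max <= 0 or fc_min <= 0:
        raise ValidationError("thresholds must be positive")
    return [s for s in stats
            if s.p_value < p_max and abs(s.signed_fc) >= fc_min]


def collapse_probes(selected: list[DifferentialStats],
                    annotation: ProbeAnnotation) -> list[DEGRecord]:
    """One record per gene: drop unannotated/pseudogene probes, then per
    gene keep the probe with max |signed FC|, ties by lowest p, then
    lexicographic probe id."""
    table = annotation.table
    by_gene: dict[str, list[DifferentialStats]] = {}
    for s in selected:
        if s.probe_id not in table.index:
            continue
        row = table.loc[s.probe_id]
        gene = str(row["gene_symbol"])
        if gene == "" or bool(row["pseudogene_flag"]):
            continue
        by_gene.setdefault(gene, []).append(s)
    records = []
    for gene in sorted(by_gene):
        rep = min(by_gene[gene],
                  key=lambda s: (-abs(s.signed_fc), s.p_value, s.probe_id))
        records.append(DEGRecord(
            gene_symbol=gene,
            representative_probe=rep.probe_id,
            signed_fc=rep.signed_fc,
            p_value=rep.p_value,
            direction="UIP" if rep.signed_fc > 0 else "DIP",
        ))
    return records
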