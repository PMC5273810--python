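import numpy as np
import pytest
from scipy import stats as st

from bloodsig.errors import ConfigurationError
from bloodsig.synthetic import (SimConfig, simulate_all, simulate_expression,
                                simulate_genesets, simulate_network)
from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize("overrides", [
        {"frac_deg": 1.5},
        {"fc_range": (0.9, 2.0)},
        {"fc_range": (3.0, 2.0)},
        {"n_genes": 0},
        {"probes_per_gene_distribution": {1: 0.5, 2: 0.4}},
        {"term_size_range": (10, 5)},
    ])
    def test_bad_values_rejected(self, overrides):
        with pytest.raises(ConfigurationError):
            small_config(**overrides)

    def test_hotspots_exceeding_chromosome_rejected(self):
        # 2 hot spots of 60 genes each cannot fit a 100-gene chromosome
        with pytest.raises(ConfigurationError, match="exceeds"):
            small_config(n_genes=100, n_chromosomes=1, n_hotspots=2,
                         hotspot_span_genes=60)

    def test_too_few_degs_for_hotspots_rejected(self):
        with pytest.raises(ConfigurationError, match="3 planted DEGs"):
            small_config(frac_deg=0.01, n_hotspots=2)   # 4 DEGs < 2*3


class TestDeterminism:
    def test_same_seed_identical_artifacts(self):
        cfg = small_config(seed=7)
        a = simulate_all(cfg)
        b = simulate_all(small_config(seed=7))
        assert (a[0].values.to_numpy() == b[0].values.to_numpy()).all()
        assert a[1].table.equals(b[1].table)
        assert sorted(a[2].graph.edges(data="sign")) == \
               sorted(b[2].graph.edges(data="sign"))
        assert a[3].terms == b[3].terms
        assert a[4].to_dict() == b[4].to_dict()

    def test_same_seed_byte_identical_files(self, tmp_path):
        from bloodsig import io_formats as io
        for d in ("run1", "run2"):
            m, ann, net, gs, _ = simulate_all(small_config(seed=3))
            out = tmp_path / d
            out.mkdir()
            io.write_expression(m, out / "m.tsv", out / "s.csv")
            io.write_annotation(ann, out / "a.tsv")
            io.write_network(net, out / "e.tsv", out / "g.tsv")
            io.write_gmt(gs, out / "t.gmt")
        for name in ("m.tsv", "s.csv", "a.tsv", "e.tsv", "g.tsv", "t.gmt"):
            assert (tmp_path / "run1" / name).read_bytes() == \
                   (tmp_path / "run2" / name).read_bytes()

    def test_different_seeds_differ(self):
        a, *_ = simulate_expression(small_config(seed=1))
        b, *_ = simulate_expression(small_config(seed=2))
        assert not a.values.equals(b.values)


class TestExpressionTruth:
    def test_deg_count_bookkeeping(self):
        cfg = small_config(n_genes=100, n_chromosomes=1, frac_deg=0.1,
                           n_hotspots=1, hotspot_span_genes=20)
        matrix, annotation, truth = simulate_expression(cfg)
        assert len(truth.deg_genes) == 10
        annotated_genes = set(annotation.table["gene_symbol"])
        assert set(truth.deg_genes) <= annotated_genes

    def test_matrix_dimensions(self, small_bundle):
        matrix, annotation, *_ = small_bundle
        cfg = small_config(seed=42)
        assert matrix.n_samples == cfg.n_cases + cfg.n_controls
        assert matrix.n_probes == len(annotation)

    def test_planted_shift_matches_truth_fc(self):
        # with zero noise the case-control log2 gap is exactly log2|FC|
        cfg = small_config(noise_sd=0.0, seed=5)
        matrix, annotation, truth = simulate_expression(cfg)
        gene_of = annotation.table["gene_symbol"].to_dict()
        cases = matrix.samples_in_group("case")
        ctrls = matrix.samples_in_group("control")
        diff = (matrix.values[cases].mean(axis=1)
                - matrix.values[ctrls].mean(axis=1))
        checked = 0
        for probe, gene in gene_of.items():
            fc = truth.deg_genes.get(gene)
            expected = np.sign(fc) * np.log2(abs(fc)) if fc else 0.0
            assert diff[probe] == pytest.approx(expected, abs=1e-9)
            checked += fc is not None
        assert checked > 0

    def test_hotspot_intervals_hold_at_least_three_degs(self, small_bundle):
        _, annotation, _, _, truth = small_bundle
        from bloodsig.hotspots import order_genome
        ordered = order_genome(annotation)
        for chrom, lo, hi in truth.hotspot_intervals:
            genes = list(ordered[chrom]["gene"])[lo:hi + 1]
            assert sum(g in truth.deg_genes for g in genes) >= 3

    def test_null_type_one_error_near_nominal(self):
        """frac_deg=0: two-sample t-test rejects at ~ alpha."""
        alpha, rejections, total = 0.05, 0, 0
        for seed in range(40):
            cfg = small_config(n_genes=100, frac_deg=0.0, n_hotspots=0,
                               seed=1000 + seed)
            m, _, _ = simulate_expression(cfg)
            cases = m.values[m.samples_in_group("case")].to_numpy()
            ctrls = m.values[m.samples_in_group("control")].to_numpy()
            _, p = st.ttest_ind(cases, ctrls, axis=1, equal_var=False)
            rejections += (p < alpha).sum()
            total += len(p)
        rate = rejections / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) < 4 * se + 0.005


class TestNetwork:
    def test_many_to_one_mapping_exists(self, small_bundle):
        net = small_bundle[2]
        objects = list(net.gene_to_object.values())
        assert len(set(objects)) < len(objects)

    def test_planted_hub_neighborhoods(self, small_bundle):
        _, _, net, _, truth = small_bundle
        deg_objects = {net.gene_to_object[g] for g in truth.deg_genes}
        assert truth.hub_objects
        for hub in truth.hub_objects:
            nbrs = net.neighbors_undirected(hub)
            frac = len(nbrs & deg_objects) / len(nbrs)
            assert frac >= 0.5 - 1e-9

    def test_impossible_hub_demand_rejected(self):
        cfg = small_config(frac_deg=0.06, hub_neighborhood_deg_frac=1.0,
                           n_genes=100, n_chromosomes=1, n_hotspots=1,
                           network_nodes=3000, network_attachment=5)
        _, _, truth = simulate_expression(cfg)
        # only ~6 DEG objects exist but high-degree hubs need ~all
        # neighbors replaced; expect the configuration error
        with pytest.raises(ConfigurationError):
            simulate_network(cfg, truth)

    def test_degree_distribution_heavy_tailed(self, small_bundle):
        net = small_bundle[2]
        degrees = np.array([len(net.neighbors_undirected(o))
                            for o in net.objects])
        assert degrees.max() > 5 * np.median(degrees)


class TestGenesets:
    def test_enriched_terms_share_deg_members(self, small_bundle):
        _, _, _, collection, truth = small_bundle
        deg = set(truth.deg_genes)
        for term_id, _, members in collection:
            frac = len(set(members) & deg) / len(members)
            if term_id in truth.enriched_terms:
                assert frac >= 0.6 - 1e-9
            else:
                assert frac < 0.6

    def test_term_sizes_in_range(self, small_bundle):
        _, _, _, collection, _ = small_bundle
        lo, hi = small_config().term_size_range
        for _, _, members in collection:
            assert lo <= len(members) <= hi
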