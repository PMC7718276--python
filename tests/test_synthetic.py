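"""The synthetic-data generators: determinism and statistical structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mraxis.synthetic import (
    NetworkSimConfig,
    PlantConfig,
    VariantSimConfig,
    plant_regulator,
    random_gene_annotation,
    simulate_coverage,
    simulate_expression_matrix,
    simulate_network,
    simulate_variant_calls,
)


def edge_tuples(edges):
    return [(e.source, e.target, e.kind, e.confidence) for e in edges]


class TestSimulateNetwork:
    def test_deterministic_given_seed(self):
        cfg = NetworkSimConfig(n_tfs=10, n_target_genes=50, seed=5)
        assert edge_tuples(simulate_network(cfg)) == edge_tuples(simulate_network(cfg))

    def test_different_seeds_differ(self):
        a = simulate_network(NetworkSimConfig(n_tfs=10, n_target_genes=50, seed=1))
        b = simulate_network(NetworkSimConfig(n_tfs=10, n_target_genes=50, seed=2))
        assert edge_tuples(a) != edge_tuples(b)

    def test_degenerate_confidence_range(self):
        cfg = NetworkSimConfig(
            n_tfs=5, n_target_genes=20, confidence_range=(1.0, 1.0), seed=0
        )
        edges = simulate_network(cfg)
        assert edges and all(e.confidence == 1.0 for e in edges)

    def test_minimal_network_edge_frequency(self):
        # one TF, one gene, mean out-degree 1: the single possible edge
        # TF001 -> G00001 appears with the Poisson-truncated frequency
        # P(K >= 1) = 1 - exp(-1)
        counts = []
        for seed in range(400):
            cfg = NetworkSimConfig(
                n_tfs=1, n_target_genes=1, tf_dna_out_degree_mean=1.0, seed=seed
            )
            edges = simulate_network(cfg)
            assert len(edges) <= 1
            if edges:
                assert (edges[0].source, edges[0].target) == ("TF001", "G00001")
            counts.append(len(edges))
        freq = np.mean(counts)
        expected = 1 - np.exp(-1)
        assert abs(freq - expected) < 3 * np.sqrt(expected * (1 - expected) / 400)

    def test_out_degree_matches_poisson_mean(self):
        totals = []
        for seed in range(60):
            cfg = NetworkSimConfig(
                n_tfs=5, n_target_genes=200, tf_dna_out_degree_mean=8.0, seed=seed
            )
            totals.append(sum(e.kind == "tf_dna" for e in simulate_network(cfg)))
        mean_deg = np.mean(totals) / 5
        assert abs(mean_deg - 8.0) < 3 * np.sqrt(8.0 / (5 * 60))

    def test_ppi_edges_are_symmetric_pairs(self):
        edges = simulate_network(NetworkSimConfig(n_tfs=20, n_target_genes=50, seed=3))
        ppi = {(e.source, e.target) for e in edges if e.kind == "ppi"}
        assert ppi == {(b, a) for a, b in ppi}

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="n_target_genes"):
            NetworkSimConfig(n_tfs=10, n_target_genes=5)
        with pytest.raises(ValueError, match="confidence_range"):
            NetworkSimConfig(confidence_range=(0.9, 0.2))


class TestPlantRegulator:
    def setup_edges(self, seed=0, **kw):
        cfg = NetworkSimConfig(n_tfs=20, n_target_genes=400, seed=seed, **kw)
        return simulate_network(cfg)

    def test_deterministic(self):
        edges = self.setup_edges()
        t1, _ = plant_regulator(edges, PlantConfig("TF001", seed=9))
        t2, _ = plant_regulator(edges, PlantConfig("TF001", seed=9))
        pd.testing.assert_frame_equal(t1, t2)

    def test_absent_tf_raises(self):
        with pytest.raises(KeyError):
            plant_regulator(self.setup_edges(), PlantConfig("NOT_A_TF"))

    def test_null_effect_scores_indistinguishable(self):
        edges = self.setup_edges()
        table, truth = plant_regulator(
            edges, PlantConfig("TF001", effect_mean=0.0, seed=2)
        )
        planted = set(truth["member_depths"])
        scores = np.sign(table["log2_fc"]) * -np.log10(
            np.maximum(table["adj_p_value"], 1e-300)
        )
        in_set = scores[table["gene"].isin(planted)]
        out_set = scores[~table["gene"].isin(planted)]
        assert stats.ks_2samp(in_set, out_set).pvalue > 0.01

    def test_null_p_values_uniform(self):
        edges = simulate_network(
            NetworkSimConfig(
                n_tfs=20, n_target_genes=5000, tf_dna_out_degree_mean=400.0, seed=1
            )
        )
        table, _ = plant_regulator(edges, PlantConfig("TF001", effect_mean=0.0, seed=3))
        assert len(table) >= 4000
        assert stats.kstest(table["p_value"], "uniform").pvalue > 0.01

    def test_strong_effect_separates_direct_targets(self):
        diffs = []
        for seed in range(10):
            edges = self.setup_edges(seed=seed)
            table, truth = plant_regulator(
                edges, PlantConfig("TF001", effect_mean=5.0, noise_sd=1.0, seed=seed)
            )
            scores = np.sign(table["log2_fc"]) * -np.log10(
                np.maximum(table["adj_p_value"], 1e-300)
            )
            d1 = {g for g, d in truth["member_depths"].items() if d == 1}
            background = ~table["gene"].isin(set(truth["member_depths"]))
            diffs.append(
                scores[table["gene"].isin(d1)].mean() - scores[background].mean()
            )
        assert np.mean(diffs) >= 3.0

    def test_depth_attenuation_of_planted_effect(self):
        edges = self.setup_edges(seed=4)
        table, truth = plant_regulator(
            edges, PlantConfig("TF001", effect_mean=4.0, depth_decay=0.5, seed=5)
        )
        fc = dict(zip(table["gene"], table["log2_fc"]))
        means = {}
        for d in (1, 2, 3):
            members = [g for g, dd in truth["member_depths"].items() if dd == d]
            if len(members) >= 5:
                means[d] = np.mean([fc[g] for g in members])
        depths = sorted(means)
        assert all(means[a] > means[b] for a, b in zip(depths, depths[1:]))


class TestSimulateExpression:
    SETS = {"hot": {f"S{i}" for i in range(20)}, "cold": {f"C{i}" for i in range(20)}}

    def test_nonnegative_and_deterministic(self):
        m1 = simulate_expression_matrix(3, self.SETS, "hot", 2.0, seed=1)
        m2 = simulate_expression_matrix(3, self.SETS, "hot", 2.0, seed=1)
        pd.testing.assert_frame_equal(m1, m2)
        assert (m1.to_numpy() >= 0).all()

    def test_unknown_set_rejected(self):
        with pytest.raises(KeyError):
            simulate_expression_matrix(3, self.SETS, "missing", 2.0)

    def test_null_shift_gives_null_t_statistics(self):
        mat = simulate_expression_matrix(20, self.SETS, "hot", 0.0, seed=2)
        g1 = np.log(mat.iloc[:, :20].to_numpy())
        g2 = np.log(mat.iloc[:, 20:].to_numpy())
        t, p = stats.ttest_ind(g1, g2, axis=1)
        # p-values approximately uniform => mean ~0.5, few small ones
        assert abs(np.mean(p) - 0.5) < 0.05
        assert np.mean(p < 0.05) < 0.12

    def test_shifted_set_rises_in_group_two(self):
        from mraxis.enrichment import ssgsea

        higher = 0
        for seed in range(10):
            mat = simulate_expression_matrix(3, self.SETS, "hot", 3.0, seed=seed)
            es = ssgsea(mat, {"hot": self.SETS["hot"]}, normalize=False)
            wide = es.pivot(index="set", columns="sample", values="es").loc["hot"]
            g1 = wide[[c for c in wide.index if c.startswith("grp1")]].mean()
            g2 = wide[[c for c in wide.index if c.startswith("grp2")]].mean()
            higher += g2 > g1
        assert higher >= 9


class TestSimulateVariants:
    def test_deterministic(self):
        c1, b1, t1 = simulate_variant_calls(VariantSimConfig(seed=8))
        c2, b2, t2 = simulate_variant_calls(VariantSimConfig(seed=8))
        assert b1 == b2 and t1 == t2
        assert {k: [v.key for v in vs] for k, vs in c1.items()} == {
            k: [v.key for v in vs] for k, vs in c2.items()
        }

    def test_call_set_structure(self):
        cfg = VariantSimConfig(seed=0)
        calls, blacklist, truth = simulate_variant_calls(cfg)
        assert len(calls) == 2 * cfg.n_normals
        assert len(truth) == cfg.n_true_somatic
        assert len(blacklist) == cfg.n_strain_variants
        for (caller, normal), recs in calls.items():
            keys = {v.key for v in recs}
            assert truth <= keys  # true somatics in every pair
            assert blacklist <= keys  # strain variants in every pair

    def test_caller_specific_false_positives(self):
        calls, blacklist, truth = simulate_variant_calls(VariantSimConfig(seed=1))
        varscan = set.intersection(
            *[{v.key for v in vs} for (c, n), vs in calls.items() if c == "varscan"]
        )
        mutect = set.intersection(
            *[{v.key for v in vs} for (c, n), vs in calls.items() if c == "mutect2"]
        )
        fp_varscan = varscan - truth - blacklist
        assert fp_varscan and not (fp_varscan & mutect)


class TestSimulateCoverage:
    def test_total_depletion_zeroes_promoters(self):
        ann = random_gene_annotation(n_genes=10, seed=0)
        depleted = list(ann["name"][:3])
        cov = simulate_coverage(ann, depleted, depletion_factor=0.0, flank=500)
        for gene in depleted:
            row = ann[ann["name"] == gene].iloc[0]
            tss = row["start"] if row["strand"] == "+" else row["end"]
            inside = cov[(cov["start"] <= tss) & (cov["end"] > tss)]
            assert (inside["value"] == 0.0).all()

    def test_depleted_to_background_ratio(self):
        ann = random_gene_annotation(n_genes=20, seed=1)
        depleted = list(ann["name"][:5])
        factor = 0.3
        cov = simulate_coverage(ann, depleted, depletion_factor=factor, flank=800)
        from mraxis.tss import profile_density, tss_windows

        wd = tss_windows(ann, depleted, flank=800)
        wn = tss_windows(ann, list(ann["name"][5:]), flank=800)
        pd_ = profile_density(cov, wd, bin_size=800, flank=800)
        pn = profile_density(cov, wn, bin_size=800, flank=800)
        ratio = pd_.mean_density.mean() / pn.mean_density.mean()
        assert abs(ratio - factor) <= 0.1 * max(factor, 0.1)

    def test_deterministic_track(self):
        ann = random_gene_annotation(n_genes=8, seed=2)
        c1 = simulate_coverage(ann, list(ann["name"][:2]), 0.5, seed=7)
        c2 = simulate_coverage(ann, list(ann["name"][:2]), 0.5, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_unknown_gene_rejected(self):
        ann = random_gene_annotation(n_genes=5, seed=3)
        with pytest.raises(KeyError):
            simulate_coverage(ann, ["nope"], 0.5)

    def test_track_is_valid_bedgraph(self):
        ann = random_gene_annotation(n_genes=12, seed=4)
        cov = simulate_coverage(ann, list(ann["name"][:4]), 0.2, flank=1000)
        starts, ends = cov["start"].to_numpy(), cov["end"].to_numpy()
        assert (starts < ends).all()
        assert (starts[1:] >= ends[:-1]).all()
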