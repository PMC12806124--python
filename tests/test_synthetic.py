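"""Synthetic-data generator: determinism, planted effects, truth consistency."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tbgenes import (GeneSet, SimConfig, score_signature,
                     simulate_multi_tissue_bulk,
                     simulate_single_cell_trajectory, simulate_study,
                     simulate_tumor_nat_pairs, write_fixture_bundle)
from tbgenes.exceptions import ConfigError, DesignError
from tbgenes.synthetic import SimTruth, config_with


def _planted_effects(matrix, design, truth):
    """Empirical home-vs-best-other mean log2 difference per planted gene."""
    df = matrix.to_frame()
    labels = design.align_to(matrix)
    means = df.T.groupby(labels.to_numpy()).mean().T
    out = {}
    for g, home in truth.tb_gene_map.items():
        others = means.loc[g].drop(home)
        out[g] = means.loc[g, home] - others.max()
    return pd.Series(out)


class TestConfig:
    def test_invalid_fields_named(self):
        with pytest.raises(ConfigError, match="n_tissues"):
            SimConfig(n_tissues=0)
        with pytest.raises(ConfigError, match="frac_tb_down"):
            SimConfig(frac_tb_down=1.5)
        with pytest.raises(ConfigError, match="stemness_coupling"):
            SimConfig(stemness_coupling=0.3)

    def test_from_dict_rejects_unknown_fields(self):
        with pytest.raises(ConfigError, match="bogus"):
            SimConfig.from_dict({"bogus": 1})


class TestMultiTissueBulk:
    def test_same_seed_bit_identical(self, small_config):
        m1, _, _ = simulate_multi_tissue_bulk(small_config)
        m2, _, _ = simulate_multi_tissue_bulk(small_config)
        assert np.array_equal(m1.values, m2.values)

    def test_different_seed_differs(self, small_config):
        m1, _, _ = simulate_multi_tissue_bulk(small_config)
        m2, _, _ = simulate_multi_tissue_bulk(config_with(small_config, seed=99))
        assert not np.array_equal(m1.values, m2.values)

    def test_noise_free_planted_effect_exact(self, small_config):
        cfg = config_with(small_config, noise_sd=0.0, planted_log2fc=2.0)
        m, d, truth = simulate_multi_tissue_bulk(cfg)
        eff = _planted_effects(m, d, truth)
        assert np.allclose(eff, 2.0)

    def test_mean_planted_effect_close_at_default_noise(self):
        cfg = SimConfig(planted_log2fc=2.0, noise_sd=0.5,
                        samples_per_tissue=50, seed=21)
        m, d, truth = simulate_multi_tissue_bulk(cfg)
        eff = _planted_effects(m, d, truth)
        # the max-over-others comparison biases each effect slightly low;
        # the mean across planted genes stays within the Monte-Carlo band
        assert abs(eff.mean() - 2.0) < 0.2

    def test_truth_genes_exist_and_inclusions_hold(self, small_config):
        m, _, truth = simulate_multi_tissue_bulk(small_config)
        genes = set(m.gene_ids)
        assert set(truth.tb_gene_map) <= genes
        assert set(truth.stemness_genes) <= genes
        assert truth.candidate_genes <= truth.down_genes <= set(truth.tb_gene_map)

    def test_background_genes_share_mean_across_tissues(self, small_config):
        cfg = config_with(small_config, noise_sd=0.0)
        m, d, truth = simulate_multi_tissue_bulk(cfg)
        df = m.to_frame().loc[list(truth.background_genes)]
        labels = d.align_to(m)
        means = df.T.groupby(labels.to_numpy()).mean().T
        assert np.allclose(means.to_numpy(), means.to_numpy()[:, [0]])

    def test_truth_inclusion_violation_rejected(self):
        with pytest.raises(Exception, match="down_genes"):
            SimTruth(tb_gene_map={"a": "T01"}, down_genes={"zzz"},
                     candidate_genes=set(), down_log2fc={}, stemness_genes=(),
                     background_genes=(), baseline_log2={"a": 1.0},
                     tissues=("T01",), focal_tissue="T01")


class TestTumorNatPairs:
    def test_unknown_tissue_rejected(self, small_config):
        _, _, truth = simulate_multi_tissue_bulk(small_config)
        with pytest.raises(DesignError):
            simulate_tumor_nat_pairs(small_config, truth, "T99")

    def test_no_downregulation_when_frac_zero(self, small_config):
        cfg = config_with(small_config, frac_tb_down=0.0, n_candidates=0,
                          noise_sd=0.0)
        _, _, truth = simulate_multi_tissue_bulk(cfg)
        pair = simulate_tumor_nat_pairs(cfg, truth, truth.focal_tissue)
        non_stem = [g for g in pair.tumor.gene_ids
                    if g not in set(truth.stemness_genes)]
        tsub = pair.tumor.subset(genes=non_stem)
        nsub = pair.nat.subset(genes=non_stem)
        assert np.allclose(tsub.values, nsub.values)

    def test_planted_downregulation_power_at_stated_n(self):
        # 40 pairs, 1 log2-unit shift: >=95% of down genes reach q < 0.05
        from tbgenes import differential_expression
        cfg = SimConfig(n_tumor_pairs=40, tumor_down_log2fc=1.0, seed=31)
        _, _, truth = simulate_multi_tissue_bulk(cfg)
        pair = simulate_tumor_nat_pairs(cfg, truth, truth.focal_tissue)
        de = differential_expression(pair.tumor, pair.nat).set_index("gene_id")
        focal_down = [g for g in truth.down_genes
                      if truth.tb_gene_map[g] == truth.focal_tissue]
        frac = (de.loc[focal_down, "q"] < 0.05).mean()
        assert frac >= 0.95

    def test_pairing_index_recorded(self, small_config):
        _, _, truth = simulate_multi_tissue_bulk(small_config)
        pair = simulate_tumor_nat_pairs(small_config, truth, truth.focal_tissue)
        assert len(pair.pairs) == small_config.n_tumor_pairs
        assert set(pair.pairs["tumor_sample"]) == set(pair.tumor.sample_ids)
        assert set(pair.pairs["nat_sample"]) == set(pair.nat.sample_ids)


class TestSingleCellTrajectory:
    def test_too_many_clusters_rejected(self, small_config):
        _, _, truth = simulate_multi_tissue_bulk(small_config)
        cfg = config_with(small_config, n_cells=3, n_cell_clusters=10)
        with pytest.raises(ConfigError):
            simulate_single_cell_trajectory(cfg, truth)

    def test_zero_coupling_decouples_programs(self):
        cfg = SimConfig(stemness_coupling=0.0, n_cells=2000, seed=41)
        _, _, truth = simulate_multi_tissue_bulk(cfg)
        counts, cells = simulate_single_cell_trajectory(cfg, truth)
        tb = score_signature(counts, GeneSet(
            "TB", tuple(truth.tb_genes_for(truth.focal_tissue))))
        stem = score_signature(counts, GeneSet("ST", truth.stemness_genes))
        rho = spearmanr(tb.scores, stem.scores).statistic
        assert abs(rho) < 0.1

    def test_strong_coupling_anticorrelates_programs(self):
        cfg = SimConfig(stemness_coupling=-0.8, n_cells=2000, seed=42)
        _, _, truth = simulate_multi_tissue_bulk(cfg)
        counts, cells = simulate_single_cell_trajectory(cfg, truth)
        tb = score_signature(counts, GeneSet(
            "TB", tuple(truth.tb_genes_for(truth.focal_tissue))))
        stem = score_signature(counts, GeneSet("ST", truth.stemness_genes))
        assert spearmanr(tb.scores, stem.scores).statistic <= -0.5

    def test_tb_program_decays_and_stemness_rises(self):
        cfg = SimConfig(n_cells=1500, seed=43)
        _, _, truth = simulate_multi_tissue_bulk(cfg)
        counts, cells = simulate_single_cell_trajectory(cfg, truth)
        pt = pd.Series(cells["pseudotime"].to_numpy(), index=cells["cell_id"])
        from tbgenes import score_trend
        tb = score_signature(counts, GeneSet(
            "TB", tuple(truth.tb_genes_for(truth.focal_tissue))))
        stem = score_signature(counts, GeneSet("ST", truth.stemness_genes))
        assert score_trend(tb, pt).rho < -0.5
        assert score_trend(stem, pt).rho > 0.5

    def test_degenerate_pseudotime_collapses_to_one_cluster(self, small_config):
        _, _, truth = simulate_multi_tissue_bulk(small_config)
        counts, cells = simulate_single_cell_trajectory(
            small_config, truth, pseudotime=np.zeros(small_config.n_cells))
        assert cells["cluster"].nunique() == 1

    def test_clusters_partition_pseudotime(self, small_config):
        _, _, truth = simulate_multi_tissue_bulk(small_config)
        _, cells = simulate_single_cell_trajectory(small_config, truth)
        bounds = cells.groupby("cluster")["pseudotime"].agg(["min", "max"])
        bounds = bounds.sort_values("min")
        assert (bounds["min"].to_numpy()[1:] >=
                bounds["max"].to_numpy()[:-1]).all()


class TestFixtureBundle:
    def test_round_trip_and_checksums(self, small_config, tmp_path):
        from tbgenes import io as tbio
        study = simulate_study(small_config)
        manifest = write_fixture_bundle(study, tmp_path)
        back = tbio.read_expression_tsv(tmp_path / "bulk_expression.tsv",
                                        unit_scale="log2")
        assert np.array_equal(back.values, study.bulk.values)
        sc_back = tbio.read_mtx_bundle(tmp_path)
        assert np.array_equal(sc_back.values, study.sc_counts.values)
        truth_back = SimTruth.from_dict(
            json.loads((tmp_path / "truth.json").read_text()))
        assert truth_back.tb_gene_map == study.truth.tb_gene_map
        # checksum changes iff content changes
        tsv = tmp_path / "tissue_design.tsv"
        before = manifest["files"]["tissue_design.tsv"]
        manifest2 = write_fixture_bundle(study, tmp_path)
        assert manifest2["files"]["tissue_design.tsv"] == before
        tsv.write_text(tsv.read_text() + "# touched\n")
        from tbgenes.synthetic import _sha256
        assert _sha256(tsv) != before

    def test_bundle_feeds_discovery_without_warnings(self, small_config, tmp_path):
        import warnings
        from tbgenes import discover_tb_genes
        from tbgenes import io as tbio
        study = simulate_study(small_config)
        write_fixture_bundle(study, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            m = tbio.read_expression_tsv(tmp_path / "bulk_expression.tsv",
                                         unit_scale="log2")
            d = tbio.read_design_tsv(tmp_path / "tissue_design.tsv")
            table = discover_tb_genes(m, d)
        assert table["is_tb"].any()

    def test_unwritable_path_raises_io_error(self, small_config):
        study = simulate_study(small_config)
        with pytest.raises(OSError):
            write_fixture_bundle(study, "/proc/definitely/not/writable")
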