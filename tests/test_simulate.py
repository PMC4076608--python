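"""Generator determinism, planted-effect bookkeeping and sampling properties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methcross import simulate
from methcross.io import SampleMeta, classify_context
from methcross.simulate import (
    ConfigError,
    TruthConfig,
    build_truth_model,
    load_truth_tables,
    simulate_sample,
    write_truth_tables,
)


class TestBuildTruthModel:
    def test_same_seed_identical(self, small_config):
        a = build_truth_model(small_config, seed=5)
        b = build_truth_model(small_config, seed=5)
        assert a.sequences_b6 == b.sequences_b6
        assert a.snps.equals(b.snps)
        assert a.strain_sites.equals(b.strain_sites)
        for chrom in a.chroms:
            np.testing.assert_array_equal(a.baseline_levels[chrom],
                                          b.baseline_levels[chrom])

    def test_planted_counts_match_config(self, small_config, small_truth):
        assert len(small_truth.strain_sites) == small_config.n_strain_sites
        assert len(small_truth.sex_sites) == small_config.n_sex_sites
        assert len(small_truth.imprinted_regions) == small_config.n_imprinted_regions
        assert (small_truth.strain_sites["delta"]
                == small_config.strain_delta).all()

    def test_effect_sites_disjoint(self, small_truth):
        seen: set[tuple[str, int]] = set()
        for table in (small_truth.strain_sites, small_truth.sex_sites,
                      small_truth.epimutation_sites):
            for r in table.itertuples(index=False):
                assert (r.chrom, r.pos) not in seen
                seen.add((r.chrom, r.pos))
        for r in small_truth.imprinted_regions.itertuples(index=False):
            cpgs = small_truth.cpg_positions[r.chrom]
            for i in range(r.first_idx, r.first_idx + r.n_cpgs):
                assert (r.chrom, int(cpgs[i])) not in seen

    def test_imprinted_regions_span_at_least_ten_cpgs(self, small_truth):
        assert (small_truth.imprinted_regions["n_cpgs"] >= 10).all()

    def test_infeasible_config_rejected(self):
        cfg = TruthConfig(n_regions=1, region_length=300, n_strain_sites=500)
        with pytest.raises(ConfigError):
            build_truth_model(cfg, seed=0)

    def test_cpg_map_matches_context_classification(self, small_truth):
        """Every recorded CpG classifies as CG on both haplotypes."""
        for chrom in small_truth.chroms:
            seq_b6 = small_truth.sequences_b6[chrom]
            seq_dba = small_truth.sequences_dba[chrom]
            for pos in small_truth.cpg_positions[chrom][:50]:
                assert classify_context(seq_b6, int(pos), "+") == "CG"
                # SNP placement never touches CpGs, so the map is shared
                assert classify_context(seq_dba, int(pos), "+") == "CG"

    def test_snp_alleles_differ_between_haplotypes(self, small_truth):
        for r in small_truth.snps.itertuples(index=False):
            assert r.b6 != r.dba
            assert small_truth.sequences_b6[r.chrom][r.pos - 1] == r.b6
            assert small_truth.sequences_dba[r.chrom][r.pos - 1] == r.dba


class TestSimulateSample:
    def test_error_free_full_methylation_is_all_M(self):
        cfg = TruthConfig(n_regions=1, region_length=800, error_rate=0.0,
                          sample_jitter_sd=0.0, cg_mean=0.75,
                          n_strain_sites=0, n_sex_sites=0,
                          n_imprinted_regions=0, n_epimutation_sites=0)
        truth = build_truth_model(cfg, seed=3)
        for chrom in truth.chroms:  # force every CpG fully methylated
            truth.baseline_levels[chrom][:] = 1.0
        sim = simulate_sample(truth, SampleMeta.from_group("B6_F", "B6", "F"),
                              seed=4)
        assert all(set(r.states) == {"M"} for r in sim.epireads)

    def test_parent_reads_single_genotype(self, clean_dataset):
        for read in clean_dataset["DBA_M"].epireads:
            assert read.true_allele == "DBA"

    def test_f1_reads_both_genotypes(self, clean_dataset):
        alleles = {r.true_allele for r in clean_dataset["BXD_F"].epireads}
        assert alleles == {"B6", "DBA"}

    def test_mean_coverage_near_configured(self, small_truth, small_dataset):
        sites = [s for s in small_dataset["B6_F"].sites if s.context == "CG"]
        mean_cov = np.mean([s.total_count for s in sites])
        assert abs(mean_cov - small_truth.config.coverage_mean) \
            < 0.05 * small_truth.config.coverage_mean

    def test_same_seed_identical_sample(self, small_truth):
        meta = SampleMeta.from_group("BXD_M", "BXD", "M")
        a = simulate_sample(small_truth, meta, seed=9)
        b = simulate_sample(small_truth, meta, seed=9)
        assert a.epireads == b.epireads
        assert a.sites == b.sites

    def test_imprinted_level_follows_origin_not_genotype(self, clean_truth,
                                                         clean_dataset):
        """Maternal alleles are highly methylated in both cross directions."""
        region = clean_truth.imprinted_regions.iloc[0]
        positions = set(
            int(p) for p in clean_truth.cpg_positions[region.chrom]
            [region.first_idx:region.first_idx + region.n_cpgs])
        for cross, maternal in (("BXD_F", "B6"), ("DXB_F", "DBA")):
            by_allele = {"B6": [], "DBA": []}
            for read in clean_dataset[cross].epireads:
                if read.chrom != region.chrom:
                    continue
                for pos, state in zip(read.cpg_positions, read.states):
                    if pos in positions and state != "N":
                        by_allele[read.true_allele].append(state == "M")
            maternal_level = np.mean(by_allele[maternal])
            paternal = "DBA" if maternal == "B6" else "B6"
            paternal_level = np.mean(by_allele[paternal])
            assert maternal_level > 0.85
            assert paternal_level < 0.15

    def test_baselines_converge_at_large_n(self):
        """Law-of-large-numbers check on per-context baselines, ~10k CpGs."""
        cfg = TruthConfig(n_regions=80, region_length=2000,
                          n_strain_sites=0, n_sex_sites=0,
                          n_imprinted_regions=0, n_epimutation_sites=0,
                          noncg_keep_fraction=0.05)
        truth = build_truth_model(cfg, seed=33)
        cg = np.concatenate([truth.baseline_levels[c] for c in truth.chroms])
        assert len(cg) > 8000
        assert abs(cg.mean() - cfg.cg_mean) < 3 * cg.std() / np.sqrt(len(cg))
        for ctx, mean in (("CHG", cfg.chg_mean), ("CHH", cfg.chh_mean)):
            lv = truth.noncg_sites.query("context == @ctx")["level"]
            assert abs(lv.mean() - mean) < 3 * lv.std() / np.sqrt(len(lv))


class TestTruthTables:
    def test_roundtrip(self, small_truth, tmp_path):
        write_truth_tables(small_truth, tmp_path)
        loaded = load_truth_tables(tmp_path)
        for name in ("strain_sites", "sex_sites", "epimutation_sites"):
            orig = getattr(small_truth, name).reset_index(drop=True)
            pd.testing.assert_frame_equal(loaded[name], orig,
                                          check_dtype=False)
        assert (tmp_path / "imprinted_regions.bed").exists()

    def test_zero_effect_model_writes_empty_tables(self, tmp_path):
        cfg = TruthConfig(n_regions=1, region_length=600, n_strain_sites=0,
                          n_sex_sites=0, n_imprinted_regions=0,
                          n_epimutation_sites=0)
        truth = build_truth_model(cfg, seed=1)
        write_truth_tables(truth, tmp_path)
        loaded = load_truth_tables(tmp_path)
        assert loaded["strain_sites"].empty
        assert list(loaded["strain_sites"].columns) \
            == list(truth.strain_sites.columns)
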