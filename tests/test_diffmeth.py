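"""Site statistics against independent oracles and threshold boundaries."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from methcross.diffmeth import (
    PRESETS,
    ComparisonSpec,
    MethDataError,
    bin_counts,
    binomial_ci,
    detect_epimutations,
    genes_near_sites,
    group_ttest,
    pairwise_site_test,
    screen_sites,
    variance_ks,
)
from methcross.io import CytosineSite, GenomicInterval, sites_to_frame


def cp_oracle(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson bounds by direct bisection on binomial tails."""
    if k == 0:
        lower = 0.0
    else:
        lower = optimize.brentq(
            lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-13)
    if k == n:
        upper = 1.0
    else:
        upper = optimize.brentq(
            lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-13)
    return lower, upper


class TestBinomialCi:
    def test_boundaries(self):
        assert binomial_ci(0, 10)[0] == 0.0
        assert binomial_ci(10, 10)[1] == 1.0

    @pytest.mark.parametrize("k,n", [(5, 10), (1, 10), (9, 10), (3, 25),
                                     (30, 60), (59, 60), (0, 7), (7, 7)])
    def test_matches_tail_inversion_oracle(self, k, n):
        lo, hi = binomial_ci(k, n)
        olo, ohi = cp_oracle(k, n)
        assert lo == pytest.approx(olo, abs=1e-9)
        assert hi == pytest.approx(ohi, abs=1e-9)

    def test_vectorized_matches_scalar(self):
        k = np.array([0, 3, 10])
        n = np.array([10, 10, 10])
        lo, hi = binomial_ci(k, n)
        for i in range(3):
            slo, shi = binomial_ci(int(k[i]), int(n[i]))
            assert lo[i] == pytest.approx(slo)
            assert hi[i] == pytest.approx(shi)

    def test_n_zero_rejected(self):
        with pytest.raises(MethDataError):
            binomial_ci(0, 0)


def site(pos, k=5, n=20, chrom="chr1"):
    return CytosineSite(chrom, pos, "+", "CG", k, n)


def site_frame(positions, chrom="chr1"):
    return sites_to_frame([site(p, chrom=chrom) for p in positions])


class TestPairwiseSiteTest:
    def test_identical_sites_not_significant(self):
        r = pairwise_site_test(site(5, 12, 20), site(5, 12, 20))
        assert not r.significant and r.delta == 0

    def test_mutual_ci_exclusion_with_large_delta(self):
        a, b = site(5, 18, 20), site(5, 2, 20)
        r = pairwise_site_test(a, b)
        assert r.delta == pytest.approx(0.8)
        # verify the criterion against the CI oracle
        lo_a, hi_a = cp_oracle(18, 20)
        lo_b, hi_b = cp_oracle(2, 20)
        assert (b.level < lo_a or b.level > hi_a)
        assert (a.level < lo_b or a.level > hi_b)
        assert r.significant

    def test_low_coverage_excluded(self):
        r = pairwise_site_test(site(5, 9, 9), site(5, 0, 20))
        assert not r.significant

    def test_symmetric_in_arguments(self):
        for ka, kb in ((18, 2), (10, 10), (20, 9)):
            a, b = site(5, ka, 20), site(5, kb, 20)
            assert pairwise_site_test(a, b).significant \
                == pairwise_site_test(b, a).significant

    def test_coordinate_mismatch_rejected(self):
        with pytest.raises(MethDataError):
            pairwise_site_test(site(5, 1, 20), site(6, 1, 20))


class TestGroupTtest:
    def test_identical_groups(self):
        t, p = group_ttest([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_zero_variance_unequal_means(self):
        t, p = group_ttest([0, 0, 0, 0], [1, 1, 1, 1])
        assert p < 1e-300

    def test_matches_pooled_formula(self):
        a = [0.31, 0.45, 0.52, 0.38]
        b = [0.71, 0.69, 0.58, 0.80, 0.75]
        t, p = group_ttest(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
            / (na + nb - 2)
        t_direct = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_direct = 2 * stats.t.sf(abs(t_direct), na + nb - 2)
        assert t == pytest.approx(t_direct, abs=1e-10)
        assert p == pytest.approx(p_direct, abs=1e-10)

    def test_too_few_values_rejected(self):
        with pytest.raises(MethDataError):
            group_ttest([0.5], [0.4, 0.6])


def unit_tables(fractions_by_unit, n=100, pos=50):
    """One-site tables with exact methylation fractions per unit."""
    tables = {}
    for unit, frac in fractions_by_unit.items():
        tables[unit] = sites_to_frame(
            [site(pos, round(frac * n), n)])
    return tables


class TestScreenSites:
    def test_sex_preset_large_difference_significant(self):
        tables = unit_tables({"f1": 0.92, "f2": 0.88, "f3": 0.91, "f4": 0.89,
                              "m1": 0.11, "m2": 0.09, "m3": 0.12, "m4": 0.08})
        groups = {u: ("A" if u.startswith("f") else "B") for u in tables}
        res = screen_sites(tables, groups, PRESETS["sex"])
        assert len(res) == 1 and bool(res.significant[0])

    def test_sex_preset_small_delta_rejected_despite_tiny_p(self):
        tables = unit_tables({"f1": 0.20, "f2": 0.20, "f3": 0.20, "f4": 0.20,
                              "m1": 0.05, "m2": 0.05, "m3": 0.05, "m4": 0.05})
        groups = {u: ("A" if u.startswith("f") else "B") for u in tables}
        res = screen_sites(tables, groups, PRESETS["sex"])
        assert res.p_value[0] < 1e-3 and res.delta[0] < 0.2
        assert not bool(res.significant[0])

    def test_imprinting_preset_needs_p_below_1e6(self):
        fr_a = {"a1": 0.70, "a2": 0.50, "a3": 0.60, "a4": 0.62}
        fr_b = {"b1": 0.45, "b2": 0.35, "b3": 0.40, "b4": 0.38}
        tables = unit_tables({**fr_a, **fr_b})
        groups = {u: ("A" if u.startswith("a") else "B") for u in tables}
        res = screen_sites(tables, groups, PRESETS["imprinting"])
        _, p = group_ttest(list(fr_a.values()), list(fr_b.values()))
        assert res.p_value[0] == pytest.approx(p, rel=1e-9)
        assert bool(res.significant[0]) == (p < 1e-6)
        assert p > 1e-6  # this configuration is not strong enough

    def test_undercovered_units_skipped(self):
        tables = unit_tables({"a1": 0.9, "a2": 0.9, "a3": 0.9,
                              "b1": 0.1, "b2": 0.1, "b3": 0.1})
        tables["b3"] = sites_to_frame([site(50, 0, 5)])  # below min coverage
        groups = {u: u[0].upper() for u in tables}
        spec = ComparisonSpec("group_ttest", "sex", min_group_size=3)
        res = screen_sites(tables, groups, spec)
        assert len(res) == 0  # B group drops to 2 usable replicates


class TestDetectEpimutations:
    def make_tables(self, parent_k, parent_n, f1_k, f1_n, pos=30):
        parents = {"B6_F": sites_to_frame([site(pos, parent_k, parent_n)]),
                   "B6_M": sites_to_frame([site(pos, parent_k, parent_n)])}
        f1 = {("BXD_F", "B6"): sites_to_frame([site(pos, f1_k, f1_n)]),
              ("BXD_M", "B6"): sites_to_frame([site(pos, f1_k, f1_n)])}
        strains = {"B6_F": "B6", "B6_M": "B6"}
        return parents, f1, strains

    def test_strong_shift_called_in_two_pairs(self):
        parents, f1, strains = self.make_tables(0, 30, 25, 30)
        calls, summary = detect_epimutations(parents, f1, strains)
        # 2 parents x 2 F1s sharing the B6 allele -> 4 consistent pairs
        assert len(calls) == 4
        assert summary.n_pairs[0] == 4 and bool(summary.class_ge2[0])
        assert calls.delta.iloc[0] == pytest.approx(25 / 30, abs=1e-12)

    def test_same_sex_restriction_halves_pairs(self):
        parents, f1, strains = self.make_tables(0, 30, 25, 30)
        sex_of = {"B6_F": "F", "B6_M": "M", "BXD_F": "F", "BXD_M": "M"}
        calls, summary = detect_epimutations(parents, f1, strains,
                                             sex_of=sex_of)
        assert len(calls) == 2
        assert set(zip(calls.parent_sample, calls.f1_sample)) \
            == {("B6_F", "BXD_F"), ("B6_M", "BXD_M")}

    def test_known_imprinted_site_excluded(self):
        parents, f1, strains = self.make_tables(0, 30, 25, 30)
        known = [GenomicInterval("chr1", 10, 60)]
        calls, summary = detect_epimutations(parents, f1, strains, known)
        assert calls.empty and summary.empty

    def test_small_shift_not_called(self):
        parents, f1, strains = self.make_tables(10, 30, 19, 30)  # delta 0.3
        calls, _ = detect_epimutations(parents, f1, strains)
        assert calls.empty


class TestVarianceKs:
    @staticmethod
    def rows_with_variances(variances):
        """Two-column level matrix whose per-site variances are as given."""
        return np.array([[0.0, np.sqrt(2.0 * v)] for v in variances])

    def test_identical_regimes(self):
        m = self.rows_with_variances([0.01, 0.02, 0.03])
        d, p, fold = variance_ks(m, m)
        assert d == 0.0 and fold == pytest.approx(1.0)

    def test_separated_variances_match_enumeration_oracle(self):
        inter = self.rows_with_variances([4.0, 5.0, 6.0])
        intra = self.rows_with_variances([1.0, 2.0, 3.0])
        d, p, fold = variance_ks(inter, intra)
        assert d == 1.0
        # exact null: all C(6,3) label assignments of the pooled variances
        pooled = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        n_extreme = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            stat = stats.ks_2samp(a, b).statistic
            n_extreme += stat >= 1.0
        assert p == pytest.approx(n_extreme / 20)
        assert fold == pytest.approx(5.0 / 2.0)

    def test_planted_strain_effects_inflate_fold(self, small_truth,
                                                 small_dataset):
        """Across-strain variance exceeds within-noise variance on synthetic
        data carrying planted strain effects."""
        frames = {s: small_dataset[s].sites for s in
                  ("B6_F", "B6_M", "DBA_F", "DBA_M")}
        piv = {}
        for s, sites in frames.items():
            df = sites_to_frame(sites).query("context == 'CG'")
            piv[s] = df.set_index(["chrom", "pos"])["level"]
        mat = pd.DataFrame(piv).dropna()
        inter = mat[["B6_F", "DBA_F"]].to_numpy()
        intra = mat[["B6_F", "B6_M"]].to_numpy()  # same strain, both sexes
        # mean variance is lifted by the planted strain sites even though
        # the bulk of the distribution (sampling noise) is shared
        d, p, fold = variance_ks(inter, intra)
        assert fold > 1.0

    def test_single_sample_regime_rejected(self):
        with pytest.raises(MethDataError):
            variance_ks(np.zeros((3, 1)), np.zeros((3, 2)))


class TestBinCounts:
    def test_bin_boundaries(self):
        sites = sites_to_frame([site(100_000), site(100_001)])
        bins, _ = bin_counts(sites, {"chr1": 200_000})
        assert bins["count"].tolist() == [1, 1]

    def test_counts_conserved(self, small_dataset):
        df = sites_to_frame(small_dataset["B6_F"].sites)
        bins, _ = bin_counts(df, {c: 1500 for c in df.chrom.unique()},
                             bin_size=500)
        assert bins["count"].sum() == len(df)

    def test_zero_sites_threshold_at_least_one(self):
        bins, threshold = bin_counts(
            sites_to_frame([]).reindex(columns=["chrom", "pos", "strand"]),
            {"chr1": 300_000})
        assert (bins["count"] == 0).all()
        assert threshold >= 1

    def test_site_beyond_chromosome_rejected(self):
        with pytest.raises(MethDataError):
            bin_counts(sites_to_frame([site(500)]), {"chr1": 400})


class TestGenesNearSites:
    GENE = [GenomicInterval("chr1", 20_000, 25_000, "geneA")]

    def test_site_inside_gene_body(self):
        res = genes_near_sites(site_frame([22_000]), self.GENE)
        assert res.gene.tolist() == ["geneA"]
        assert res.min_distance[0] == 0

    def test_window_boundary_inclusive(self):
        assert len(genes_near_sites(site_frame([35_000]), self.GENE)) == 1
        assert len(genes_near_sites(site_frame([35_001]), self.GENE)) == 0

    def test_no_sites_empty_result(self):
        assert genes_near_sites(site_frame([]), self.GENE).empty
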