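"""Two-allele mixture likelihood, EM behaviour and region calling."""

from __future__ import annotations

import math

import numpy as np
import pytest

from methcross.amr import (
    EPS,
    MethDataError,
    _mixture_loglik,
    amr_scan,
    candidate_imprinted_regions,
    single_allele_loglik,
    two_allele_em,
    AmrRegion,
)
from methcross.io import EpiRead, standard_cross_samples


def read(positions, states, chrom="chr1", rid="r", sample="s"):
    return EpiRead(rid, chrom, sample, tuple(positions), states)


def matrix(rows):
    return np.array(rows, dtype=np.int8)


def direct_single_loglik(M, eps=EPS):
    """Brute-force per-cell summation oracle for the one-pattern model."""
    M = np.asarray(M)
    ll = 0.0
    for j in range(M.shape[1]):
        col = M[:, j]
        obs = col[col >= 0]
        if len(obs) == 0:
            continue
        p = min(max(obs.mean(), eps), 1 - eps)
        for s in obs:
            ll += math.log(p) if s == 1 else math.log(1 - p)
    return ll


class TestSingleAlleleLoglik:
    def test_all_methylated_boundary(self):
        M = matrix([[1, 1, 1]] * 4)
        ll, p = single_allele_loglik(M)
        assert ll == pytest.approx(12 * math.log(1 - EPS))
        assert (p == 1 - EPS).all()

    def test_half_methylated_closed_form(self):
        M = matrix([[1, 0]] * 50 + [[0, 1]] * 50)  # every CpG at 50%
        ll, p = single_allele_loglik(M)
        assert ll == pytest.approx(200 * math.log(0.5))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            M = rng.integers(-1, 2, size=(8, 5)).astype(np.int8)
            if not (M >= 0).any():
                continue
            ll, _ = single_allele_loglik(M)
            assert ll == pytest.approx(direct_single_loglik(M), abs=1e-10)

    def test_empty_window_rejected(self):
        with pytest.raises(MethDataError):
            single_allele_loglik(matrix([[-1, -1]]))


class TestTwoAlleleEm:
    def test_bimodal_reads_recover_two_profiles(self):
        """10 all-M plus 10 all-U reads: profiles split to the clamp bounds
        and the likelihood matches the closed-form mixture optimum."""
        M = matrix([[1] * 10] * 10 + [[0] * 10] * 10)
        ll, p1, p2, resp, converged = two_allele_em(M, seed=0)
        hi, lo = (p1, p2) if p1.mean() > p2.mean() else (p2, p1)
        assert (hi > 0.99).all() and (lo < 0.01).all()
        # closed form at the optimum (profiles at the clamp):
        # each read: log(0.5) + log( (1-eps)^10 + eps^10 )
        per_read = math.log(0.5) + math.log((1 - EPS) ** 10 + EPS ** 10)
        assert ll == pytest.approx(20 * per_read, abs=1e-6)
        assert converged

    def test_identical_reads_lrt_near_zero(self):
        M = matrix([[1, 0, 1, 0]] * 12)
        ll1, _ = single_allele_loglik(M)
        ll2, *_ = two_allele_em(M, seed=1)
        assert 2 * (ll2 - ll1) == pytest.approx(0.0, abs=1e-6)

    def test_label_swap_symmetry(self):
        M = matrix([[1, 1, 0, 0]] * 6 + [[0, 0, 1, 1]] * 6)
        ll, p1, p2, *_ = two_allele_em(M, seed=2)
        ll_swapped, _ = _mixture_loglik(M, p2, p1)
        assert ll_swapped == pytest.approx(ll, abs=1e-9)

    def test_fewer_than_four_reads_rejected(self):
        with pytest.raises(MethDataError):
            two_allele_em(matrix([[1, 0]] * 3))

    def test_lrt_nonnegative_and_monotone_on_random_windows(self):
        """On random data the mixture never fits worse than one pattern."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            n_reads = int(rng.integers(4, 12))
            width = int(rng.integers(2, 6))
            M = rng.integers(-1, 2, size=(n_reads, width)).astype(np.int8)
            if not (M >= 0).any():
                continue
            ll1, _ = single_allele_loglik(M)
            ll2, *_ = two_allele_em(M, n_starts=2,
                                    seed=int(rng.integers(2**31)))
            assert 2 * (ll2 - ll1) >= -1e-6


class TestPermutationP:
    def test_bimodal_window_small_p_null_window_large_p(self):
        from methcross.amr import permutation_p

        rng = np.random.default_rng(8)
        bimodal = matrix([[1] * 6] * 10 + [[0] * 6] * 10)
        null = rng.integers(0, 2, size=(20, 6)).astype(np.int8)
        p_bimodal = permutation_p(bimodal, n_perm=60, seed=1)
        p_null = permutation_p(null, n_perm=60, seed=1)
        assert p_bimodal <= 2 / 61
        assert p_null > 0.05


def window_reads(levels_a, levels_b, n_per_allele=15, start=100, step=17,
                 seed=0, chrom="chr1", sample="s"):
    """Reads drawn from two allele profiles over consecutive CpGs."""
    rng = np.random.default_rng(seed)
    positions = tuple(start + i * step for i in range(len(levels_a)))
    reads = []
    for a, levels in (("A", levels_a), ("B", levels_b)):
        for i in range(n_per_allele):
            states = "".join(
                "M" if rng.random() < lv else "U" for lv in levels)
            reads.append(EpiRead(f"{a}{i}", chrom, sample, positions, states))
    return reads


class TestAmrScan:
    def test_uniform_methylation_no_regions(self):
        levels = [0.5] * 14
        reads = window_reads(levels, levels, n_per_allele=40, seed=3)
        assert amr_scan(reads, seed=0) == []

    def test_planted_bimodal_region_recovered_once(self):
        reads = window_reads([0.95] * 12, [0.05] * 12, n_per_allele=30,
                             seed=4)
        regions = amr_scan(reads, seed=0)
        assert len(regions) == 1
        region = regions[0]
        assert region.n_cpgs >= 10
        assert region.max_delta > 0.5

    def test_low_delta_region_rejected(self):
        reads = window_reads([0.7] * 12, [0.3] * 12, n_per_allele=40, seed=5)
        regions = amr_scan(reads, delta_threshold=0.5, seed=0)
        assert regions == []

    def test_chromosome_with_too_few_cpgs_skipped(self):
        reads = window_reads([0.9] * 4, [0.1] * 4, n_per_allele=10, seed=6)
        assert amr_scan(reads, w=10, seed=0) == []


def region(chrom="chr1", start=100, end=400):
    return AmrRegion(chrom=chrom, start=start, end=end, first_cpg_index=0,
                     n_cpgs=12, best_p=1e-5, max_delta=0.9)


class TestCandidates:
    METAS = {m.sample_id: m for m in standard_cross_samples()}

    def sets(self, present):
        return {s: ([region()] if s in present else [])
                for s in self.METAS}

    def test_region_in_all_eight_samples(self):
        (c,) = candidate_imprinted_regions(self.sets(set(self.METAS)),
                                           self.METAS)
        assert c.n_samples == 8 and c.has_parent and c.has_f1

    def test_region_in_five_samples_rejected(self):
        present = {"B6_F", "B6_M", "DBA_F", "BXD_F", "BXD_M"}
        assert candidate_imprinted_regions(self.sets(present),
                                           self.METAS) == []

    def test_f1_only_region_rejected_as_asm_compatible(self):
        present = {"BXD_F", "BXD_M", "DXB_F", "DXB_M"}
        sets = self.sets(present)
        # duplicate to reach the 6-sample count without parents: still no
        for s in ("BXD_F", "BXD_M"):
            sets[s] = [region(), region(start=90, end=380)]
        assert candidate_imprinted_regions(sets, self.METAS,
                                           min_samples=4) == []

    def test_missing_sample_set_rejected(self):
        sets = self.sets(set(self.METAS))
        del sets["DXB_M"]
        with pytest.raises(MethDataError):
            candidate_imprinted_regions(sets, self.METAS)

    def test_parents_plus_f1s_make_candidate(self):
        present = {"B6_F", "B6_M", "DBA_F", "DBA_M", "BXD_F", "DXB_F"}
        (c,) = candidate_imprinted_regions(self.sets(present), self.METAS)
        assert set(c.samples_present) == present


class TestOnSyntheticData:
    def test_planted_imprinted_regions_recovered(self, small_truth,
                                                 small_amr_results):
        """AMR candidates recover every planted imprinted region and never
        overlap a planted strain-effect-only site's neighbourhood."""
        per_sample, candidates = small_amr_results
        regions = small_truth.imprinted_regions
        n_found = 0
        for r in regions.itertuples(index=False):
            n_found += any(c.chrom == r.chrom and c.start <= r.end
                           and r.start <= c.end for c in candidates)
        assert n_found / len(regions) >= 0.9
        strain_positions = {(r.chrom, r.pos) for r in
                            small_truth.strain_sites.itertuples(index=False)}
        for c in candidates:
            for chrom, pos in strain_positions:
                assert not (chrom == c.chrom and c.start <= pos <= c.end)
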