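"""Reference calibration experiments for the fixed-threshold screens.

Each function builds a synthetic two-condition dataset — a large null
background plus a block of genuine differences that defines the observed
significant count y — and calibrates the screen's simulation-based FDR by
binomial null resampling (x/y, see :mod:`methcross.fdr`).  These are the
package's standing checks that the screen thresholds control false discovery
at the documented levels:

* pairwise binomial criterion (coverage ≥10, mutual 95% CI exclusion,
  delta > 50%): FDR below 1%;
* allele t-test screen (p < 0.05, delta > 50%, two groups of per-sample
  fractions): FDR below 0.05%;
* sex t-test screen (p < 0.001, delta > 20%): FDR below 5%.
"""

from __future__ import annotations

import numpy as np

from .diffmeth import PRESETS, ComparisonSpec, masked_mean, pairwise_binomial_flags, ttest_matrix
from .fdr import FdrEstimate, estimate_fdr


def _planted_levels(rng: np.random.Generator, n: int, delta_lo: float,
                    delta_hi: float, margin: float = 0.02
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of levels separated by a delta drawn in [delta_lo, delta_hi]."""
    delta = rng.uniform(delta_lo, delta_hi, n)
    low = rng.uniform(margin, 1.0 - margin - delta)
    flip = rng.random(n) < 0.5
    a = np.where(flip, low + delta, low)
    b = np.where(flip, low, low + delta)
    return a, b


def _ttest_count_fn(spec: ComparisonSpec, n_a: int):
    def count(K: np.ndarray, N: np.ndarray) -> int:
        with np.errstate(invalid="ignore"):
            frac = np.where(N >= spec.min_coverage, K / N, np.nan)
        _, p = ttest_matrix(frac[:, :n_a], frac[:, n_a:],
                            spec.min_group_size)
        delta = np.abs(masked_mean(frac[:, :n_a])
                       - masked_mean(frac[:, n_a:]))
        ok = ~np.isnan(p)
        return int(np.sum(ok & (p < spec.p_threshold)
                          & (delta > spec.delta_threshold)))

    return count


def pairwise_binomial_fdr(seed: int = 0, n_null: int = 10_000,
                          n_true: int = 500, n_sims: int = 20,
                          cov_lo: int = 10, cov_hi: int = 100) -> FdrEstimate:
    """Calibrate the two-sample pairwise binomial criterion.

    Null sites share one level drawn Uniform(0,1) between the two samples;
    true-difference sites carry level differences of 0.6-0.9.  Coverage is
    uniform on [cov_lo, cov_hi] per sample.
    """
    rng = np.random.default_rng(seed)
    n_sites = n_null + n_true
    N = rng.integers(cov_lo, cov_hi + 1, size=(n_sites, 2)).astype(float)
    p_null = rng.random(n_null)
    pa = np.empty(n_sites)
    pb = np.empty(n_sites)
    pa[:n_null] = p_null
    pb[:n_null] = p_null
    pa[n_null:], pb[n_null:] = _planted_levels(rng, n_true, 0.6, 0.9)
    K = np.column_stack([rng.binomial(N[:, 0].astype(int), pa),
                         rng.binomial(N[:, 1].astype(int), pb)]).astype(float)
    spec = PRESETS["strain"]

    def count(Km: np.ndarray, Nm: np.ndarray) -> int:
        return int(np.sum(pairwise_binomial_flags(
            Km[:, 0], Nm[:, 0], Km[:, 1], Nm[:, 1],
            spec.min_coverage, spec.delta_threshold, spec.alpha)))

    return estimate_fdr(count, K, N, n_sims=n_sims, seed=seed + 1)


def group_ttest_fdr(spec: ComparisonSpec, seed: int = 0,
                    n_sites: int = 5000, effect_fraction: float = 0.05,
                    effect_delta: tuple[float, float] = (0.6, 0.9),
                    n_a: int = 8, n_b: int = 8, n_sims: int = 1000,
                    cov_lo: int = 10, cov_hi: int = 100) -> FdrEstimate:
    """Calibrate a two-group t-test screen under binomial null resampling.

    Every unit (replicate) draws its methylated count from its group's
    level; ``effect_fraction`` of sites carry a group difference inside
    ``effect_delta`` and define the observed significant set.
    """
    rng = np.random.default_rng(seed)
    n_units = n_a + n_b
    n_effect = int(round(n_sites * effect_fraction))
    N = rng.integers(cov_lo, cov_hi + 1, size=(n_sites, n_units)).astype(float)
    base = rng.random(n_sites)
    level_a = base.copy()
    level_b = base.copy()
    la, lb = _planted_levels(rng, n_effect, *effect_delta)
    level_a[:n_effect] = la
    level_b[:n_effect] = lb
    levels = np.column_stack([np.repeat(level_a[:, None], n_a, axis=1),
                              np.repeat(level_b[:, None], n_b, axis=1)])
    K = rng.binomial(N.astype(int), levels).astype(float)
    return estimate_fdr(_ttest_count_fn(spec, n_a), K, N,
                        n_sims=n_sims, seed=seed + 1)


def allele_ttest_fdr(seed: int = 0, n_sites: int = 5000,
                     n_sims: int = 1000) -> FdrEstimate:
    """Allele screen (p < 0.05, delta > 50%): planted differences >= 0.6
    at 5% of sites, eight per-sample fractions per allele group."""
    return group_ttest_fdr(PRESETS["allele"], seed=seed, n_sites=n_sites,
                           effect_fraction=0.05, effect_delta=(0.6, 0.9),
                           n_a=8, n_b=8, n_sims=n_sims)


def sex_ttest_fdr(seed: int = 0, n_sites: int = 5000,
                  n_sims: int = 200) -> FdrEstimate:
    """Sex screen (p < 0.001, delta > 20%): planted differences >= 0.4 at
    2% of sites, four female and four male per-sample fractions."""
    return group_ttest_fdr(PRESETS["sex"], seed=seed, n_sites=n_sites,
                           effect_fraction=0.02, effect_delta=(0.4, 0.8),
                           n_a=4, n_b=4, n_sims=n_sims)
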