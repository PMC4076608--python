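"""Simulation-based FDR, Storey q-values and hypergeometric enrichment.

The FDR of a fixed-threshold screen is calibrated by resampling: every
compared count at a site is replaced by a Binomial(n, p) draw with n the
observed coverage and p the methylation level pooled across the compared
units at that site, the screen is re-run, and the FDR is the mean null
significant count x divided by the observed significant count y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io import MethDataError


@dataclass(frozen=True)
class FdrEstimate:
    """x/y calibration of a screen: null hits over observed hits."""

    x: float        # mean significant sites per null replicate
    y: int          # significant sites in the observed data
    fdr: float      # x / y
    n_sims: int
    seed: int


@dataclass(frozen=True)
class QValueResult:
    p_values: np.ndarray
    pi0: float
    lambda_: float
    q_values: np.ndarray


def pooled_levels(K: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Per-site methylation level pooled across the compared units."""
    K = np.asarray(K, dtype=float)
    N = np.asarray(N, dtype=float)
    total = np.nansum(N, axis=1)
    meth = np.nansum(K, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, meth / total, 0.0)
    return p


def simulate_null(K: np.ndarray, N: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Structure-preserving null draw: Binomial(n_unit, p_pooled) per cell.

    The coverage pattern (including missing cells, NaN in ``N``) is kept;
    only methylated counts are resampled under the no-difference null.
    """
    N = np.asarray(N, dtype=float)
    p = pooled_levels(K, N)
    n_int = np.nan_to_num(N, nan=0.0).astype(np.int64)
    draws = rng.binomial(n_int, p[:, None]).astype(float)
    draws[np.isnan(N)] = np.nan
    return draws


def estimate_fdr(
    screen_fn: Callable[[np.ndarray, np.ndarray], int],
    K: np.ndarray,
    N: np.ndarray,
    n_sims: int = 1000,
    seed: int = 0,
) -> FdrEstimate:
    """Simulation-based FDR of any site screen.

    ``screen_fn(K, N) -> int`` counts significant sites for count matrices of
    the screen's layout (sites × compared units).  The observed count y must
    be positive, otherwise the ratio is undefined.
    """
    y = int(screen_fn(K, N))
    if y == 0:
        raise MethDataError("estimate_fdr undefined: no significant sites "
                            "in the observed data (y = 0)")
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_sims)
    for i in range(n_sims):
        null_counts[i] = screen_fn(simulate_null(K, N, rng), N)
    x = float(null_counts.mean())
    return FdrEstimate(x=x, y=y, fdr=x / y, n_sims=n_sims, seed=seed)


def storey_qvalue(p_values: Sequence[float], lambda_: float = 0.5) -> QValueResult:
    """Storey q-values with a fixed pi0 tuning threshold.

    pi0 is estimated as the fraction of p-values above ``lambda_`` rescaled
    by 1-lambda (capped at 1); q-values follow by enforcing monotonicity of
    pi0·m·p/rank over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise MethDataError("storey_qvalue on empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise MethDataError("p-values outside [0, 1]")
    m = p.size
    pi0 = min(1.0, float(np.mean(p > lambda_)) / (1.0 - lambda_))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(p_values=p, pi0=pi0, lambda_=lambda_, q_values=q)


def hypergeom_enrichment(hits_in_list: int, list_size: int,
                         category_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric enrichment P(X >= hits).

    ``list_size`` genes are drawn from a universe containing
    ``category_size`` category members; the p-value is the exact probability
    of at least the observed overlap.
    """
    if not (0 <= hits_in_list <= min(list_size, category_size)
            <= universe_size):
        raise MethDataError(
            f"inconsistent counts: hits={hits_in_list}, list={list_size}, "
            f"category={category_size}, universe={universe_size}")
    return float(stats.hypergeom.sf(hits_in_list - 1, universe_size,
                                    category_size, list_size))
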