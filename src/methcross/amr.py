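"""Genotype-independent detection of allelically methylated regions (AMRs).

An AMR is an interval where sequencing reads segregate into two distinct
methylation patterns — the signature of two epialleles, whether caused by a
genotype difference or by parent-of-origin imprinting.  Detection slides a
fixed-width window of consecutive CpGs along the genome and compares, by
likelihood ratio, a single-pattern model (one per-CpG Bernoulli level) with
an equal-weight two-component mixture over reads, fitted by EM.  Significant
overlapping windows are merged into maximal regions.

Candidate imprinted regions are then nominated by cross-sample intersection:
an AMR present in most samples *including at least one inbred parent* cannot
be genotype-driven (parental chromosomes are genotypically identical), so
parental presence is what separates imprinting from allele-specific
methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import EpiRead, GenomicInterval, MethDataError, SampleMeta

log = logging.getLogger(__name__)

EPS = 1e-3  # clamp for fitted per-CpG levels


@dataclass
class AmrWindow:
    """Likelihood-ratio evidence for two methylation alleles in one window."""

    chrom: str
    first_cpg_index: int
    width: int
    n_reads: int
    logl_single: float
    logl_two: float
    lrt: float
    p_value: float
    profile_1: np.ndarray
    profile_2: np.ndarray
    delta: float
    converged: bool = True


@dataclass
class AmrRegion:
    """Merged run of significant windows: >= width consecutive CpGs."""

    chrom: str
    start: int            # 1-based first CpG position
    end: int              # 1-based last CpG position
    first_cpg_index: int
    n_cpgs: int
    best_p: float
    max_delta: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# likelihood models
# ---------------------------------------------------------------------------

def _state_matrix(reads: Sequence[EpiRead], pos_to_col: Mapping[int, int],
                  width: int) -> np.ndarray:
    """Reads × CpGs matrix over {1 meth, 0 unmeth, -1 missing}."""
    M = np.full((len(reads), width), -1, dtype=np.int8)
    for i, r in enumerate(reads):
        for pos, state in zip(r.cpg_positions, r.states):
            j = pos_to_col.get(pos)
            if j is None or state == "N":
                continue
            M[i, j] = 1 if state == "M" else 0
    return M


def single_allele_loglik(M: np.ndarray,
                         eps: float = EPS) -> tuple[float, np.ndarray]:
    """Single-pattern model: per-CpG Bernoulli MLE, clamped to [eps, 1-eps].

    Returns the maximized log-likelihood and the fitted per-CpG levels.
    Columns with no observed state contribute nothing (level reported 0.5).
    """
    meth = (M == 1)
    obs = (M >= 0)
    tot = obs.sum(axis=0)
    if tot.sum() == 0:
        raise MethDataError("window has zero observed states")
    with np.errstate(invalid="ignore"):
        p = np.where(tot > 0, meth.sum(axis=0) / np.maximum(tot, 1), 0.5)
    p = np.clip(p, eps, 1.0 - eps)
    ll = float((meth * np.log(p)).sum() + ((M == 0) * np.log1p(-p)).sum())
    return ll, p


def _mixture_loglik(M: np.ndarray, p1: np.ndarray, p2: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Log-likelihood of the equal-weight two-pattern mixture + responsibilities."""
    meth = (M == 1)
    unmeth = (M == 0)
    l1 = meth @ np.log(p1) + unmeth @ np.log1p(-p1)
    l2 = meth @ np.log(p2) + unmeth @ np.log1p(-p2)
    lse = np.logaddexp(l1, l2)
    ll = float(np.sum(np.log(0.5) + lse))
    resp = np.exp(l1 - lse)
    return ll, resp


def two_allele_em(
    M: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_starts: int = 5,
    seed: int = 0,
    eps: float = EPS,
    history: list[list[float]] | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Fit the equal-weight two-pattern read mixture by EM.

    E-step: read responsibilities from per-CpG Bernoulli products; M-step:
    responsibility-weighted per-CpG levels (clamped).  The best of
    ``n_starts`` random initializations plus one perturbation of the
    single-pattern fit is kept, which guarantees the mixture log-likelihood
    is never below the single-pattern one.  Passing a list as ``history``
    appends one per-iteration log-likelihood trace per start.  Returns
    (logL, profile_1, profile_2, responsibilities, converged).
    """
    if M.shape[0] < 4:
        raise MethDataError("two_allele_em needs >= 4 reads")
    rng = np.random.default_rng(seed)
    meth = (M == 1)
    unmeth = (M == 0)
    obs = meth | unmeth
    width = M.shape[1]
    _, p_single = single_allele_loglik(M, eps)

    # the duplicated single-pattern fit is an EM fixed point whose likelihood
    # equals the one-pattern model, so the LRT can never go negative; the
    # perturbed split gives EM a symmetric direction to break towards
    inits = [(p_single.copy(), p_single.copy()),
             (np.clip(p_single + 0.1, eps, 1 - eps),
              np.clip(p_single - 0.1, eps, 1 - eps))]
    for _ in range(n_starts):
        inits.append((rng.uniform(eps, 1 - eps, width),
                      rng.uniform(eps, 1 - eps, width)))

    best = None
    for p1, p2 in inits:
        p1, p2 = p1.copy(), p2.copy()
        prev = -np.inf
        converged = False
        trace: list[float] = []
        for _ in range(max_iter):
            ll, resp = _mixture_loglik(M, p1, p2)
            trace.append(ll)
            if ll - prev < tol and np.isfinite(prev):
                converged = True
                break
            prev = ll
            w1 = resp[:, None]
            w2 = 1.0 - w1
            d1 = (w1 * obs).sum(axis=0)
            d2 = (w2 * obs).sum(axis=0)
            with np.errstate(invalid="ignore"):
                p1 = np.where(d1 > 0, (w1 * meth).sum(axis=0) / np.maximum(d1, 1e-12), 0.5)
                p2 = np.where(d2 > 0, (w2 * meth).sum(axis=0) / np.maximum(d2, 1e-12), 0.5)
            p1 = np.clip(p1, eps, 1 - eps)
            p2 = np.clip(p2, eps, 1 - eps)
        ll, resp = _mixture_loglik(M, p1, p2)
        trace.append(ll)
        if history is not None:
            history.append(trace)
        if best is None or ll > best[0]:
            best = (ll, p1, p2, resp, converged)
    ll, p1, p2, resp, converged = best
    if not converged:
        log.debug("two_allele_em: best start not converged after %d "
                  "iterations", max_iter)
    return ll, p1, p2, resp, converged


def fit_window(reads: Sequence[EpiRead], cpg_positions: Sequence[int],
               chrom: str, first_cpg_index: int, seed: int = 0,
               n_starts: int = 5, eps: float = EPS,
               max_iter: int = 200, tol: float = 1e-8) -> AmrWindow:
    """Fit both models on one window and form the LRT (chi-square, df=width)."""
    width = len(cpg_positions)
    pos_to_col = {int(p): j for j, p in enumerate(cpg_positions)}
    M = _state_matrix(reads, pos_to_col, width)
    M = M[(M >= 0).any(axis=1)]
    ll1, _ = single_allele_loglik(M, eps)
    ll2, p1, p2, _, converged = two_allele_em(
        M, n_starts=n_starts, seed=seed, eps=eps,
        max_iter=max_iter, tol=tol)
    lrt = 2.0 * (ll2 - ll1)
    observed_cols = (M >= 0).any(axis=0)
    if observed_cols.any():
        delta = float(np.abs(p1 - p2)[observed_cols].mean())
    else:
        delta = 0.0
    p_value = float(stats.chi2.sf(max(lrt, 0.0), df=width))
    return AmrWindow(chrom=chrom, first_cpg_index=first_cpg_index,
                     width=width, n_reads=M.shape[0],
                     logl_single=ll1, logl_two=ll2, lrt=lrt,
                     p_value=p_value, profile_1=p1, profile_2=p2,
                     delta=delta, converged=converged)


def permutation_p(M: np.ndarray, n_perm: int = 200, seed: int = 0,
                  n_starts: int = 2, eps: float = EPS) -> float:
    """Empirical LRT p-value by shuffling states within CpG columns.

    Column-wise shuffling preserves per-CpG methylation levels while breaking
    read-level phase, the signal the mixture model detects.  Provided as a
    calibration alternative to the chi-square reference distribution, which
    is not exact at a mixture boundary.
    """
    rng = np.random.default_rng(seed)
    ll1, _ = single_allele_loglik(M, eps)
    ll2, *_ = two_allele_em(M, n_starts=n_starts, seed=seed, eps=eps)
    obs_lrt = 2.0 * (ll2 - ll1)
    hits = 0
    Mp = M.copy()
    for i in range(n_perm):
        for j in range(M.shape[1]):
            col = Mp[:, j]
            obs_idx = np.flatnonzero(col >= 0)
            col[obs_idx] = col[obs_idx][rng.permutation(len(obs_idx))]
        l1, _ = single_allele_loglik(Mp, eps)
        l2, *_ = two_allele_em(Mp, n_starts=n_starts,
                               seed=seed + i + 1, eps=eps)
        if 2.0 * (l2 - l1) >= obs_lrt:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def amr_scan(
    epireads: Iterable[EpiRead],
    w: int = 10,
    p_threshold: float = 0.01,
    delta_threshold: float = 0.5,
    min_reads: int = 4,
    n_starts: int = 2,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[AmrRegion]:
    """Slide a w-CpG window along each chromosome and merge significant hits.

    The CpG index is built from the reads themselves; chromosomes with fewer
    than ``w`` CpGs are skipped.  A window is significant when its LRT
    p-value is below ``p_threshold`` and the mean absolute difference between
    the two fitted profiles exceeds ``delta_threshold``; overlapping
    significant windows merge into maximal regions carrying the minimum p and
    maximum delta.

    Scan-level EM settings trade a little optimizer polish for speed: the
    deterministic split of the single-pattern fit plus two random starts,
    with a 1e-6 convergence tolerance, resolves the LRT far more finely than
    the 0.01 significance threshold requires.
    """
    by_chrom: dict[str, list[EpiRead]] = {}
    for r in epireads:
        by_chrom.setdefault(r.chrom, []).append(r)

    regions: list[AmrRegion] = []
    for chrom in sorted(by_chrom):
        reads = by_chrom[chrom]
        cpgs = np.array(sorted({p for r in reads for p in r.cpg_positions}))
        if len(cpgs) < w:
            continue
        col_of = {int(p): i for i, p in enumerate(cpgs)}
        spans = np.array([[col_of[r.cpg_positions[0]],
                           col_of[r.cpg_positions[-1]]] for r in reads])
        order = np.argsort(spans[:, 0])
        reads = [reads[i] for i in order]
        spans = spans[order]

        sig: list[tuple[int, float, float]] = []  # (window start, p, delta)
        lo_ptr = 0
        for i in range(len(cpgs) - w + 1):
            window_cols = (i, i + w - 1)
            while lo_ptr < len(reads) and spans[lo_ptr, 1] < i:
                lo_ptr += 1
            window_reads = []
            j = lo_ptr
            while j < len(reads) and spans[j, 0] <= window_cols[1]:
                if spans[j, 1] >= i:
                    window_reads.append(reads[j])
                j += 1
            if len(window_reads) < min_reads:
                continue
            win = fit_window(window_reads, cpgs[i:i + w], chrom, i,
                             seed=seed + i, n_starts=n_starts,
                             max_iter=max_iter, tol=tol)
            if win.p_value < p_threshold and win.delta > delta_threshold:
                sig.append((i, win.p_value, win.delta))

        # merge overlapping significant windows
        for start_i, p, delta in sig:
            end_i = start_i + w - 1
            if regions and regions[-1].chrom == chrom and \
                    start_i <= regions[-1].first_cpg_index + regions[-1].n_cpgs - 1:
                last = regions[-1]
                last.n_cpgs = end_i - last.first_cpg_index + 1
                last.end = int(cpgs[end_i])
                last.best_p = min(last.best_p, p)
                last.max_delta = max(last.max_delta, delta)
            else:
                regions.append(AmrRegion(
                    chrom=chrom, start=int(cpgs[start_i]),
                    end=int(cpgs[end_i]), first_cpg_index=start_i,
                    n_cpgs=w, best_p=p, max_delta=delta))
    return regions


# ---------------------------------------------------------------------------
# cross-sample intersection
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    """A cross-sample AMR cluster nominated as putatively imprinted."""

    chrom: str
    start: int
    end: int
    samples_present: tuple[str, ...]
    n_samples: int
    has_parent: bool
    has_f1: bool
    best_p: float
    max_delta: float


def candidate_imprinted_regions(
    per_sample_regions: Mapping[str, Sequence[AmrRegion]],
    sample_meta: Mapping[str, SampleMeta],
    min_samples: int = 6,
) -> list[CandidateRegion]:
    """Intersect per-sample AMRs and nominate imprinted candidates.

    Regions from all samples are clustered by any-overlap linkage; a cluster
    is a candidate when present in at least ``min_samples`` of the samples
    AND in at least one parental and one F1 animal.  Parental presence is
    required because inbred parents are genotypically homozygous, so a
    parental AMR cannot be explained by allele-specific methylation.
    """
    missing = set(sample_meta) - set(per_sample_regions)
    if missing:
        raise MethDataError(f"missing AMR sets for samples {sorted(missing)}")

    tagged: list[tuple[str, AmrRegion]] = []
    for sample_id, regions in per_sample_regions.items():
        tagged.extend((sample_id, r) for r in regions)
    tagged.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end))

    clusters: list[list[tuple[str, AmrRegion]]] = []
    cur_chrom, cur_end = None, -1
    for sample_id, region in tagged:
        if region.chrom == cur_chrom and region.start <= cur_end:
            clusters[-1].append((sample_id, region))
            cur_end = max(cur_end, region.end)
        else:
            clusters.append([(sample_id, region)])
            cur_chrom, cur_end = region.chrom, region.end

    out: list[CandidateRegion] = []
    for cluster in clusters:
        samples = tuple(sorted({s for s, _ in cluster}))
        if len(samples) < min_samples:
            continue
        gens = {sample_meta[s].generation for s in samples}
        has_parent = "parent" in gens
        has_f1 = "F1" in gens
        if not (has_parent and has_f1):
            continue
        out.append(CandidateRegion(
            chrom=cluster[0][1].chrom,
            start=min(r.start for _, r in cluster),
            end=max(r.end for _, r in cluster),
            samples_present=samples, n_samples=len(samples),
            has_parent=has_parent, has_f1=has_f1,
            best_p=min(r.best_p for _, r in cluster),
            max_delta=max(r.max_delta for _, r in cluster)))
    return out
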