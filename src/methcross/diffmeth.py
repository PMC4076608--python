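"""Site-level differential methylation statistics.

Two test families cover all screens:

* a pairwise binomial criterion for comparing two individual samples — each
  sample's methylation fraction must fall outside the other's exact 95%
  Clopper–Pearson interval and the absolute difference must exceed a delta
  threshold (default 50%), at sites covered by ≥10 reads; and
* a two-group pooled-variance t-test over per-sample (or per-allele)
  methylation fractions, with preset p/delta thresholds for the allele
  (p<0.05, delta>50%), sex (p<0.001, delta>20%) and imprinting (p<1e-6)
  screens.

Multiple testing is handled by the fixed thresholds together with
simulation-based FDR (see :mod:`methcross.fdr`), not by per-site correction.
The module also provides intergenerational epimutation detection with
reproducibility classes, the inter- versus intra-strain variance comparison,
100-kb genome binning with a Poisson significance threshold, and gene
proximity annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CytosineSite, GenomicInterval, MethDataError, sites_to_frame

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# comparison specs / presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonSpec:
    """Thresholds of one screen; presets encode the four standard screens."""

    test: str  # pairwise_binomial | group_ttest
    grouping: str
    p_threshold: float = 0.05
    delta_threshold: float = 0.5
    min_coverage: int = 10
    min_group_size: int = 3
    alpha: float = 0.05  # CI level for the pairwise binomial criterion

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise MethDataError("p_threshold outside (0, 1]")
        if not 0 <= self.delta_threshold <= 1:
            raise MethDataError("delta_threshold outside [0, 1]")


PRESETS: dict[str, ComparisonSpec] = {
    "strain": ComparisonSpec("pairwise_binomial", "strain",
                             delta_threshold=0.5),
    "allele": ComparisonSpec("group_ttest", "allele",
                             p_threshold=0.05, delta_threshold=0.5),
    "sex": ComparisonSpec("group_ttest", "sex",
                          p_threshold=1e-3, delta_threshold=0.2),
    "imprinting": ComparisonSpec("group_ttest", "parent_of_origin",
                                 p_threshold=1e-6, delta_threshold=0.0),
    "epimutation": ComparisonSpec("pairwise_binomial", "parent_vs_F1",
                                  delta_threshold=0.5),
}


@dataclass(frozen=True)
class SiteTestResult:
    """Outcome of one two-group comparison at one site."""

    chrom: str
    pos: int
    strand: str
    level_a: float
    level_b: float
    n_a: int
    n_b: int
    delta: float
    significant: bool
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    p_value: float | None = None


# ---------------------------------------------------------------------------
# binomial confidence interval & pairwise criterion
# ---------------------------------------------------------------------------

def binomial_ci(k, n, alpha: float = 0.05):
    """Exact equal-tailed (Clopper–Pearson) binomial confidence interval.

    Vectorized over ``k`` and ``n``; the bounds are the standard beta-quantile
    form of the tail-probability inversion.  Scalar inputs return floats.
    """
    k_arr = np.asarray(k, dtype=np.int64)
    n_arr = np.asarray(n, dtype=np.int64)
    if np.any(n_arr < 1):
        raise MethDataError("binomial_ci needs n >= 1")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise MethDataError("binomial_ci needs 0 <= k <= n")
    with np.errstate(invalid="ignore"):
        lower = stats.beta.ppf(alpha / 2, k_arr, n_arr - k_arr + 1)
        upper = stats.beta.ppf(1 - alpha / 2, k_arr + 1, n_arr - k_arr)
    lower = np.where(k_arr == 0, 0.0, lower)
    upper = np.where(k_arr == n_arr, 1.0, upper)
    if np.isscalar(k) and np.isscalar(n):
        return float(lower), float(upper)
    return lower, upper


def pairwise_binomial_flags(
    k_a, n_a, k_b, n_b,
    min_coverage: int = 10, delta_threshold: float = 0.5,
    alpha: float = 0.05,
) -> np.ndarray:
    """Vectorized pairwise criterion: mutual CI exclusion + delta + coverage."""
    k_a, n_a = np.asarray(k_a), np.asarray(n_a)
    k_b, n_b = np.asarray(k_b), np.asarray(n_b)
    covered = (n_a >= min_coverage) & (n_b >= min_coverage)
    # avoid n=0 in the CI computation; such sites are never significant
    safe_na = np.maximum(n_a, 1)
    safe_nb = np.maximum(n_b, 1)
    lvl_a = k_a / safe_na
    lvl_b = k_b / safe_nb
    lo_a, hi_a = binomial_ci(np.minimum(k_a, safe_na), safe_na, alpha)
    lo_b, hi_b = binomial_ci(np.minimum(k_b, safe_nb), safe_nb, alpha)
    outside = ((lvl_b < lo_a) | (lvl_b > hi_a)) & ((lvl_a < lo_b) | (lvl_a > hi_b))
    return covered & outside & (np.abs(lvl_a - lvl_b) > delta_threshold)


def pairwise_site_test(site_a: CytosineSite, site_b: CytosineSite,
                       spec: ComparisonSpec | None = None) -> SiteTestResult:
    """Compare one site between two individual samples.

    Significant iff both samples are covered at ``min_coverage``, each
    sample's level lies outside the other's CI, and the level difference
    exceeds the delta threshold.  Symmetric in its arguments.
    """
    spec = spec or PRESETS["strain"]
    if site_a.key != site_b.key:
        raise MethDataError(
            f"coordinate mismatch: {site_a.key} vs {site_b.key}")
    ci_a = binomial_ci(site_a.meth_count, site_a.total_count, spec.alpha)
    ci_b = binomial_ci(site_b.meth_count, site_b.total_count, spec.alpha)
    sig = bool(pairwise_binomial_flags(
        site_a.meth_count, site_a.total_count,
        site_b.meth_count, site_b.total_count,
        spec.min_coverage, spec.delta_threshold, spec.alpha)[()])
    return SiteTestResult(
        chrom=site_a.chrom, pos=site_a.pos, strand=site_a.strand,
        level_a=site_a.level, level_b=site_b.level,
        n_a=site_a.total_count, n_b=site_b.total_count,
        delta=abs(site_a.level - site_b.level),
        significant=sig, ci_a=ci_a, ci_b=ci_b)


def pairwise_screen(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    spec: ComparisonSpec | None = None) -> pd.DataFrame:
    """Run the pairwise criterion over all sites shared by two site tables."""
    spec = spec or PRESETS["strain"]
    keys = ["chrom", "pos", "strand"]
    merged = table_a.merge(table_b, on=keys, suffixes=("_a", "_b"))
    if merged.empty:
        return merged.assign(level_a=[], level_b=[], delta=[], significant=[])
    flags = pairwise_binomial_flags(
        merged["meth_count_a"].to_numpy(), merged["total_count_a"].to_numpy(),
        merged["meth_count_b"].to_numpy(), merged["total_count_b"].to_numpy(),
        spec.min_coverage, spec.delta_threshold, spec.alpha)
    out = merged[keys].copy()
    if "context_a" in merged:
        out["context"] = merged["context_a"]
    out["level_a"] = merged["meth_count_a"] / merged["total_count_a"]
    out["level_b"] = merged["meth_count_b"] / merged["total_count_b"]
    out["n_a"] = merged["total_count_a"]
    out["n_b"] = merged["total_count_b"]
    out["delta"] = (out["level_a"] - out["level_b"]).abs()
    out["significant"] = flags
    return out


# ---------------------------------------------------------------------------
# group t-test
# ---------------------------------------------------------------------------

def group_ttest(values_a: Sequence[float],
                values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance t-test on per-sample methylation fractions.

    Degenerate inputs: zero pooled variance with equal means gives p = 1;
    zero pooled variance with unequal means is an infinitely strong
    separation and is reported as p = 0 (logged as degenerate).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise MethDataError("group_ttest needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        log.warning("group_ttest: zero pooled variance with unequal means")
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def masked_mean(m: np.ndarray) -> np.ndarray:
    """Row means ignoring NaN; NaN where a row has no observations."""
    cnt = np.sum(~np.isnan(m), axis=1)
    s = np.nansum(m, axis=1)
    return np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)


def _masked_var(m: np.ndarray, mean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row sample variances (ddof=1) ignoring NaN; returns (var, count)."""
    cnt = np.sum(~np.isnan(m), axis=1)
    sumsq = np.nansum(np.square(m), axis=1)
    ss = sumsq - cnt * np.square(np.where(np.isnan(mean), 0.0, mean))
    var = np.where(cnt >= 2, np.maximum(ss, 0.0) / np.maximum(cnt - 1, 1),
                   np.nan)
    return var, cnt


def ttest_matrix(frac_a: np.ndarray, frac_b: np.ndarray,
                 min_group_size: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t-test with NaN-aware group handling.

    ``frac_a``/``frac_b`` are sites × replicates matrices of methylation
    fractions, NaN marking replicates that failed coverage.  Returns (t, p);
    rows with fewer than ``min_group_size`` usable replicates in either group
    get p = NaN.
    """
    ma = masked_mean(frac_a)
    mb = masked_mean(frac_b)
    va, ca = _masked_var(frac_a, ma)
    vb, cb = _masked_var(frac_b, mb)
    usable = (ca >= min_group_size) & (cb >= min_group_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = ca + cb - 2
        sp2 = (np.nan_to_num(ca - 1) * np.nan_to_num(va)
               + np.nan_to_num(cb - 1) * np.nan_to_num(vb)) / np.maximum(df, 1)
        se = np.sqrt(sp2 * (1.0 / np.maximum(ca, 1) + 1.0 / np.maximum(cb, 1)))
        t = (ma - mb) / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    zero_var = usable & (sp2 == 0)
    p = np.where(zero_var & (ma == mb), 1.0, p)
    p = np.where(zero_var & (ma != mb), 0.0, p)
    t = np.where(zero_var & (ma == mb), 0.0, t)
    p = np.where(usable, p, np.nan)
    return t, p


def build_group_matrices(
    tables: Mapping[str, pd.DataFrame],
    group_of: Mapping[str, str],
    min_coverage: int = 10,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pivot per-unit site tables into aligned fraction/count matrices.

    ``tables`` maps a unit (a sample, or a sample × allele split) to its site
    table; ``group_of`` maps each unit to "A" or "B".  Fractions of units
    below ``min_coverage`` at a site are NaN.  Returns (site index frame,
    frac_A, frac_B, K matrix, N matrix) with K/N columns ordered A then B.
    """
    units = list(tables)
    groups = [group_of[u] for u in units]
    if set(groups) - {"A", "B"}:
        raise MethDataError("group_of values must be 'A' or 'B'")
    frames = []
    for u in units:
        t = tables[u]
        if isinstance(t, list):
            t = sites_to_frame(t)
        frames.append(t.set_index(["chrom", "pos", "strand"])[
            ["meth_count", "total_count"]])
    index = frames[0].index
    for f in frames[1:]:
        index = index.union(f.index)
    index = index.sort_values()
    K = np.full((len(index), len(units)), np.nan)
    N = np.full((len(index), len(units)), np.nan)
    for j, f in enumerate(frames):
        f = f.reindex(index)
        K[:, j] = f["meth_count"].to_numpy()
        N[:, j] = f["total_count"].to_numpy()
    frac = np.where((N >= min_coverage), K / N, np.nan)
    a_cols = [j for j, g in enumerate(groups) if g == "A"]
    b_cols = [j for j, g in enumerate(groups) if g == "B"]
    site_frame = pd.DataFrame(index.to_list(), columns=["chrom", "pos", "strand"])
    order = a_cols + b_cols
    return site_frame, frac[:, a_cols], frac[:, b_cols], K[:, order], N[:, order]


def screen_sites(
    tables: Mapping[str, pd.DataFrame],
    group_of: Mapping[str, str],
    spec: ComparisonSpec,
) -> pd.DataFrame:
    """Apply a two-group t-test screen site-by-site.

    Returns all testable sites with group means, delta, p and a significance
    flag (p below and delta above the spec thresholds).  Sites where either
    group has fewer than ``min_group_size`` covered replicates are skipped
    (counted in the log).
    """
    if spec.test != "group_ttest":
        raise MethDataError("screen_sites drives the group t-test; use "
                            "pairwise_screen for the binomial criterion")
    site_frame, fa, fb, _, _ = build_group_matrices(
        tables, group_of, spec.min_coverage)
    t, p = ttest_matrix(fa, fb, spec.min_group_size)
    mean_a = masked_mean(fa)
    mean_b = masked_mean(fb)
    delta = np.abs(mean_a - mean_b)
    tested = ~np.isnan(p)
    out = site_frame.copy()
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["n_a"] = np.sum(~np.isnan(fa), axis=1)
    out["n_b"] = np.sum(~np.isnan(fb), axis=1)
    out["delta"] = delta
    out["t"] = t
    out["p_value"] = p
    out["significant"] = tested & (p < spec.p_threshold) & (delta > spec.delta_threshold)
    n_skipped = int((~tested).sum())
    if n_skipped:
        log.info("screen_sites: %d sites skipped (insufficient group size)",
                 n_skipped)
    return out[tested].reset_index(drop=True)


# ---------------------------------------------------------------------------
# intergenerational epimutations
# ---------------------------------------------------------------------------

def detect_epimutations(
    parent_tables: Mapping[str, pd.DataFrame],
    f1_allele_tables: Mapping[tuple[str, str], pd.DataFrame],
    parent_strain_of: Mapping[str, str],
    known_imprinted: Sequence[GenomicInterval] = (),
    spec: ComparisonSpec | None = None,
    sex_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare each parent with the genotype-matched F1 chromosome.

    For every (parent sample, F1 sample) pair sharing a strain, the pairwise
    binomial criterion is applied between the parent's site table and the
    F1's table restricted to reads of that strain's allele.  Sites inside
    known imprinted genes are excluded.  When ``sex_of`` labels the samples,
    only same-sex parent–offspring pairs are compared, so that sex-specific
    methylation is not mistaken for intergenerational change.  Returns
    (per-pair calls, per-site summary) where the summary counts
    direction-consistent significant pairs and assigns reproducibility
    classes ≥1 and ≥2.
    """
    spec = spec or PRESETS["epimutation"]
    known = list(known_imprinted)
    calls = []
    for parent_id, parent_table in parent_tables.items():
        strain = parent_strain_of[parent_id]
        for (f1_id, allele), f1_table in f1_allele_tables.items():
            if allele != strain:
                continue
            if sex_of is not None and sex_of[f1_id] != sex_of[parent_id]:
                continue
            res = pairwise_screen(parent_table, f1_table, spec)
            sig = res[res["significant"]]
            for r in sig.itertuples(index=False):
                if any(g.contains(r.chrom, r.pos) for g in known):
                    continue
                calls.append({
                    "chrom": r.chrom, "pos": r.pos, "strand": r.strand,
                    "parent_sample": parent_id, "f1_sample": f1_id,
                    "allele": strain,
                    "parent_level": r.level_a, "f1_level": r.level_b,
                    "delta": r.delta,
                    "direction": int(np.sign(r.level_b - r.level_a)),
                })
    calls_df = pd.DataFrame(calls, columns=[
        "chrom", "pos", "strand", "parent_sample", "f1_sample", "allele",
        "parent_level", "f1_level", "delta", "direction"])
    if calls_df.empty:
        summary = pd.DataFrame(columns=[
            "chrom", "pos", "strand", "allele", "n_pairs", "direction",
            "class_ge1", "class_ge2"])
        return calls_df, summary

    # reproducibility: count pairs that agree in direction at a site/allele
    grouped = calls_df.groupby(["chrom", "pos", "strand", "allele"])
    rows = []
    for (chrom, pos, strand, allele), grp in grouped:
        counts = grp["direction"].value_counts()
        direction = int(counts.idxmax())
        n_pairs = int(counts.max())
        rows.append({"chrom": chrom, "pos": pos, "strand": strand,
                     "allele": allele, "n_pairs": n_pairs,
                     "direction": direction,
                     "class_ge1": n_pairs >= 1, "class_ge2": n_pairs >= 2})
    summary = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return calls_df, summary


# ---------------------------------------------------------------------------
# variance comparison, binning, gene proximity
# ---------------------------------------------------------------------------

def variance_ks(inter_levels: np.ndarray, intra_levels: np.ndarray,
                ks_method: str = "auto") -> tuple[float, float, float]:
    """Compare per-site variance distributions between two replicate regimes.

    ``inter_levels``/``intra_levels`` are sites × samples matrices of
    methylation fractions drawn across strains and within a strain
    respectively.  Per-site variances (sample variance, ddof=1, rows with ≥2
    observations) are compared with a two-sample Kolmogorov–Smirnov test;
    the fold is the ratio of mean variances.  Returns (D, p, fold).
    """
    inter = np.asarray(inter_levels, dtype=float)
    intra = np.asarray(intra_levels, dtype=float)
    for name, m in (("inter", inter), ("intra", intra)):
        if m.ndim != 2 or m.shape[1] < 2:
            raise MethDataError(f"{name} regime needs >= 2 samples")

    def site_vars(m: np.ndarray) -> np.ndarray:
        v, counts = _masked_var(m, masked_mean(m))
        return v[counts >= 2]

    v_inter, v_intra = site_vars(inter), site_vars(intra)
    if len(v_inter) == 0 or len(v_intra) == 0:
        raise MethDataError("no sites with >= 2 observations in a regime")
    d, p = stats.ks_2samp(v_inter, v_intra, method=ks_method)
    mean_intra = v_intra.mean()
    fold = float(v_inter.mean() / mean_intra) if mean_intra > 0 else float("inf")
    return float(d), float(p), fold


def bin_counts(
    sites: pd.DataFrame | Sequence[CytosineSite],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 100_000,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Count significant sites in fixed genome bins, with a Poisson threshold.

    Bin *b* covers positions [b·bin_size + 1, (b+1)·bin_size].  The per-bin
    significance threshold is the smallest count whose Poisson upper tail
    (rate = genome-wide mean count per bin) falls below a Bonferroni-corrected
    alpha; it is at least 1 even with no sites.
    """
    if not isinstance(sites, pd.DataFrame):
        sites = sites_to_frame(list(sites))
    rows = []
    total = 0
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        counts = np.zeros(n_bins, dtype=np.int64)
        sub = sites[sites["chrom"] == chrom]
        if not sub.empty:
            pos = sub["pos"].to_numpy()
            if (pos > length).any():
                raise MethDataError(
                    f"site beyond {chrom} length {length}")
            idx = (pos - 1) // bin_size
            np.add.at(counts, idx, 1)
        total += int(counts.sum())
        for b in range(n_bins):
            rows.append({"chrom": chrom, "bin_start": b * bin_size + 1,
                         "bin_end": min((b + 1) * bin_size, length),
                         "count": int(counts[b])})
    bins = pd.DataFrame(rows)
    n_bins_total = max(len(bins), 1)
    lam = total / n_bins_total
    level = alpha / n_bins_total
    c = 1
    while stats.poisson.sf(c - 1, lam) >= level:
        c += 1
    return bins, c


def genes_near_sites(
    sites: pd.DataFrame | Sequence[CytosineSite],
    annotation: Sequence[GenomicInterval],
    window: int = 10_000,
) -> pd.DataFrame:
    """Genes whose span lies within ``window`` bp of any site.

    Distance is 0 inside the gene body; a site exactly ``window`` away still
    associates.  Sites on chromosomes absent from the annotation (and vice
    versa) are skipped with a warning.
    """
    if not isinstance(sites, pd.DataFrame):
        sites = sites_to_frame(list(sites))
    by_chrom: dict[str, np.ndarray] = {
        chrom: grp["pos"].to_numpy()
        for chrom, grp in sites.groupby("chrom")
    }
    site_chroms = set(by_chrom)
    gene_chroms = {g.chrom for g in annotation}
    missing = gene_chroms - site_chroms
    if missing and site_chroms:
        log.warning("genes_near_sites: no sites on chromosomes %s",
                    sorted(missing))
    rows = []
    for gene in annotation:
        pos = by_chrom.get(gene.chrom)
        if pos is None:
            continue
        dist = np.where(pos < gene.start, gene.start - pos,
                        np.where(pos > gene.end, pos - gene.end, 0))
        near = dist <= window
        if near.any():
            rows.append({"gene": gene.name or f"{gene.chrom}:{gene.start}-{gene.end}",
                         "chrom": gene.chrom, "start": gene.start,
                         "end": gene.end, "n_sites": int(near.sum()),
                         "min_distance": int(dist.min())})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "n_sites", "min_distance"])
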