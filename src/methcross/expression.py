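"""Expression-level validation screens.

Two screens connect methylation findings to transcription:

* an imprinting test on allelic RNA-seq counts — a 2×2 Fisher's exact test
  of cross direction (BXD, DXB) against allele genotype (B6, DBA).  A true
  parent-of-origin effect makes the allelic skew *flip* with cross direction
  (the maternal allele is B6 in BXD but DBA in DXB), whereas a cis-acting
  genotype effect keeps the same allele dominant in both crosses; the flip
  criterion separates the two signatures, which the test statistic alone
  cannot.
* a sex-difference screen on a genes × samples expression matrix — per-gene
  pooled-variance t-tests with Storey q-values and a linear-scale fold
  filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethDataError
from .diffmeth import ttest_matrix
from .fdr import storey_qvalue

ALLELIC_COLUMNS = ("bxd_b6", "bxd_dba", "dxb_b6", "dxb_dba")


def fisher_imprinting_test(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a cross-direction × genotype table.

    ``table`` is [[bxd_b6, bxd_dba], [dxb_b6, dxb_dba]].  Returns (p, odds
    ratio).  The caller is responsible for the minimum-count filter; tables
    totalling fewer than 10 counts should not be tested.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise MethDataError("fisher_imprinting_test needs a 2x2 "
                            "non-negative count table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p), float(odds)


def parental_origin_consistent(bxd_b6: int, bxd_dba: int,
                               dxb_b6: int, dxb_dba: int) -> bool:
    """True when the dominant allele flips with cross direction.

    A maternally (or paternally) expressed gene is B6-skewed in one cross and
    DBA-skewed in the other; a genotype-driven skew points the same way in
    both.  Ties in either cross are not called consistent.
    """
    d_bxd = bxd_b6 - bxd_dba
    d_dxb = dxb_b6 - dxb_dba
    return bool(d_bxd * d_dxb < 0)


def imprinting_expression_screen(
    tables: pd.DataFrame,
    p_threshold: float = 0.05,
    min_total: int = 10,
    fdr_max: float = 0.05,
    fold_min: float = 1.2,
) -> pd.DataFrame:
    """Fisher-test every gene's allelic count table and flag imprinting.

    ``tables`` needs columns gene, bxd_b6, bxd_dba, dxb_b6, dxb_dba.  Genes
    with fewer than ``min_total`` counts are filtered (not tested).  Two
    significance calls are reported: the plain p < ``p_threshold`` rule and a
    Storey-FDR < ``fdr_max`` with maternal/paternal fold > ``fold_min``
    variant; the ``parental_origin`` flag marks the direction-flip signature.
    """
    if tables.empty:
        raise MethDataError("imprinting_expression_screen on empty input")
    missing = set(("gene",) + ALLELIC_COLUMNS) - set(tables.columns)
    if missing:
        raise MethDataError(f"allelic count table missing columns {missing}")
    df = tables.copy()
    df["total"] = sum(df[c] for c in ALLELIC_COLUMNS)
    df = df[df["total"] >= min_total].reset_index(drop=True)
    if df.empty:
        return df.assign(p_value=[], q_value=[], fold=[],
                         parental_origin=[], significant=[],
                         significant_fdr=[])

    p_vals, odds, origin, folds = [], [], [], []
    for r in df.itertuples(index=False):
        p, o = fisher_imprinting_test([[r.bxd_b6, r.bxd_dba],
                                       [r.dxb_b6, r.dxb_dba]])
        p_vals.append(p)
        odds.append(o)
        origin.append(parental_origin_consistent(
            r.bxd_b6, r.bxd_dba, r.dxb_b6, r.dxb_dba))
        # maternal = B6 in BXD, DBA in DXB
        maternal = r.bxd_b6 + r.dxb_dba
        paternal = r.bxd_dba + r.dxb_b6
        hi, lo = max(maternal, paternal), max(min(maternal, paternal), 1)
        folds.append(hi / lo)
    df["p_value"] = p_vals
    df["odds_ratio"] = odds
    df["fold"] = folds
    df["parental_origin"] = origin
    if len(df) >= 10:
        df["q_value"] = storey_qvalue(df["p_value"].to_numpy()).q_values
    else:
        df["q_value"] = np.nan  # pi0 estimation unstable below ~10 tests
    df["significant"] = df["p_value"] < p_threshold
    df["significant_fdr"] = (df["q_value"] < fdr_max) & (df["fold"] > fold_min)
    return df


def sex_de_screen(
    expr: pd.DataFrame,
    sex_labels,
    fold_min: float = 1.2,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Female-versus-male differential expression with fold and FDR filters.

    ``expr`` is genes × samples; ``sex_labels`` gives 'F'/'M' per column.
    Per-gene pooled-variance t-tests feed Storey q-values; the fold is the
    larger group mean over the smaller on the linear scale.  Constant genes
    get p = 1.  Significant iff q < ``fdr_max`` and fold > ``fold_min``.
    """
    labels = list(sex_labels)
    if len(labels) != expr.shape[1]:
        raise MethDataError("one sex label per expression column required")
    f_cols = [i for i, s in enumerate(labels) if s == "F"]
    m_cols = [i for i, s in enumerate(labels) if s == "M"]
    if len(f_cols) < 2 or len(m_cols) < 2:
        raise MethDataError("need >= 2 samples per sex")
    X = expr.to_numpy(dtype=float)
    if (X < 0).any():
        raise MethDataError("negative expression values")
    A, B = X[:, f_cols], X[:, m_cols]
    t, p = ttest_matrix(A, B, min_group_size=2)
    p = np.where(np.isnan(p), 1.0, p)
    mean_f, mean_m = A.mean(axis=1), B.mean(axis=1)
    hi = np.maximum(mean_f, mean_m)
    lo = np.maximum(np.minimum(mean_f, mean_m), np.finfo(float).tiny)
    fold = hi / lo
    q = storey_qvalue(p).q_values
    return pd.DataFrame({
        "gene": expr.index,
        "mean_f": mean_f,
        "mean_m": mean_m,
        "fold": fold,
        "t": t,
        "p_value": p,
        "q_value": q,
        "significant": (q < fdr_max) & (fold > fold_min),
    }).reset_index(drop=True)
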