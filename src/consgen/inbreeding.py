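"""Pedigree, ROH-based and SNP-based inbreeding coefficients.

Three families of estimators are provided:

* ``f_ped`` — the classical pedigree coefficient, A_ii - 1 from the
  numerator relationship matrix;
* ``f_roh`` — genome fraction covered by ROH, L_ROH / L_AUTO, per length
  class (>10 Mb captures the last ~5 generations, 5-10 Mb roughly 5-10,
  1-5 Mb older inbreeding);
* ``f_snp`` — the three marker-based estimators reported by GCTA ``--ibc``:
  F1 (GRM-diagonal), F2 (excess homozygosity) and F3 (correlation between
  uniting gametes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import a_matrix
from .plinkio import MISSING, GenotypeMatrix, PedigreeTable
from .roh import CLASS_LABELS, DEFAULT_L_AUTO_KB, ROHSegment, classify_roh

logger = logging.getLogger(__name__)

ROH_CLASS_COLUMNS = {
    "1-5 Mb": "f_roh_1_5",
    "5-10 Mb": "f_roh_5_10",
    ">10 Mb": "f_roh_gt10",
}


def f_ped(ped: PedigreeTable) -> pd.Series:
    """Pedigree inbreeding coefficient per individual (A_ii - 1)."""
    A = a_matrix(ped)
    return pd.Series(np.diag(A.values) - 1.0, index=A.ids, name="f_ped")


def f_roh(
    segments: list[ROHSegment],
    sample_ids: list[str],
    l_auto_kb: float = DEFAULT_L_AUTO_KB,
) -> pd.DataFrame:
    """Per-individual F_ROH per length class plus the >1 Mb total.

    F = sum of class-restricted segment lengths / l_auto_kb.  Individuals
    without segments get 0.
    """
    cols = list(ROH_CLASS_COLUMNS.values()) + ["f_roh_gt1"]
    out = pd.DataFrame(0.0, index=list(sample_ids), columns=cols)
    labels = classify_roh(segments)
    for seg, lab in zip(segments, labels):
        if lab is None or seg.sample_id not in out.index:
            continue
        out.loc[seg.sample_id, ROH_CLASS_COLUMNS[lab]] += seg.length_kb / l_auto_kb
    out["f_roh_gt1"] = out[list(ROH_CLASS_COLUMNS.values())].sum(axis=1)
    return out


def f_snp(g: GenotypeMatrix) -> pd.DataFrame:
    """SNP-based inbreeding estimators F1/F2/F3 per individual.

    With x the a1 count, p the in-sample a1 frequency and q = 1 - p, over
    the SNPs called in the individual and polymorphic in the sample:

        F1 = mean_j (x - 2p)^2 / (2pq)  -  1
        F2 = 1 - sum_j het_j / sum_j 2 p_j q_j
        F3 = mean_j [x^2 - (1 + 2p) x + 2 p^2] / (2pq)
    """
    p = g.allele_frequencies()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for F_SNP estimation")
    p = p[poly]
    q = 1 - p
    X = g.calls[:, poly].astype(float)
    called = X != MISSING
    X[~called] = np.nan
    two_pq = 2 * p * q

    with np.errstate(invalid="ignore"):
        f1 = np.nanmean((X - 2 * p) ** 2 / two_pq, axis=1) - 1.0
        het = (X == 1).astype(float)
        het[~called] = np.nan
        f2 = 1.0 - np.nansum(het, axis=1) / (called * two_pq).sum(axis=1)
        f3 = np.nanmean((X**2 - (1 + 2 * p) * X + 2 * p**2) / two_pq, axis=1)
    return pd.DataFrame(
        {"f_snp_hat1": f1, "f_snp_hat2": f2, "f_snp_hat3": f3}, index=g.sample_ids
    )


def inbreeding_table(
    g: GenotypeMatrix,
    segments: list[ROHSegment],
    ped: PedigreeTable | None = None,
    l_auto_kb: float = DEFAULT_L_AUTO_KB,
) -> pd.DataFrame:
    """One row per genotyped individual with every estimator as a column."""
    table = f_roh(segments, g.sample_ids, l_auto_kb).join(f_snp(g))
    if ped is not None:
        table = table.join(f_ped(ped))
    return table


def correlate_inbreeding(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r (lower triangle) and p (upper) across estimators.

    Zero-variance columns yield NaN and are flagged with a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 individuals to correlate")
    cols = list(table.columns)
    n = len(cols)
    out = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = table[cols[i]], table[cols[j]]
            if x.std() == 0 or y.std() == 0:
                logger.warning("correlate_inbreeding: zero variance in %s/%s", cols[i], cols[j])
                out.iloc[j, i] = out.iloc[i, j] = np.nan
                continue
            r, p = stats.pearsonr(x, y)
            out.iloc[j, i] = r
            out.iloc[i, j] = p
    return out
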