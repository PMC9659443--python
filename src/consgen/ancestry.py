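"""Ancestry-proportion estimation at fixed K and nucleus-population
selection by lineage-proportion thresholds.

The model is the standard admixture likelihood: individual i's genotype at
SNP j is Binomial(2, sum_k q_ik f_kj), with Q the n x K matrix of ancestry
proportions (rows on the simplex) and F the K x m ancestral allele
frequencies.  Fitting is by EM from multiple random starts; the likelihood
is non-decreasing every iteration, which we assert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plinkio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_F_EPS = 1e-6

MIN_CATEGORIES = ("Min1", "Min2", "Min3", "Min4")


@dataclass
class AncestryModel:
    K: int
    Q: np.ndarray  # n x K
    F: np.ndarray  # K x m
    loglik: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must lie on the simplex")
        if (self.F < _F_EPS - 1e-12).any() or (self.F > 1 - _F_EPS + 1e-12).any():
            raise ValueError("F must be bounded away from 0 and 1")


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.5,
    window_snp: int = 50,
    step: int = 5,
) -> GenotypeMatrix:
    """Greedy windowed LD pruning.

    Within each window of ``window_snp`` SNPs, repeatedly drop the later
    SNP of any remaining pair with r^2 > ``r2_max``; slide by ``step``.
    """
    from .ldne import _nan_corrcoef

    chroms = g.chromosomes()
    keep_mask = np.ones(g.n_variants, dtype=bool)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        calls = g.calls[:, idx].astype(float)
        calls[calls == MISSING] = np.nan
        start = 0
        while start < idx.size:
            window = idx[start : start + window_snp]
            local = np.flatnonzero(keep_mask[window])
            if local.size > 1:
                sub = calls[:, start : start + window_snp][:, local]
                R2 = _nan_corrcoef(sub) ** 2
                alive = np.ones(local.size, dtype=bool)
                for a in range(local.size):
                    if not alive[a]:
                        continue
                    for b in range(a + 1, local.size):
                        if alive[b] and R2[a, b] > r2_max:
                            alive[b] = False
                keep_mask[window[local[~alive]]] = False
            start += step
    kept = np.flatnonzero(keep_mask)
    logger.info("ld_prune: kept %d of %d SNPs", kept.size, g.n_variants)
    return g.subset(variant_idx=kept)


def admixture_fit(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> AncestryModel:
    """Maximum-likelihood Q and F at fixed K by EM from random starts."""
    if K < 1:
        raise ValueError("K must be >= 1")
    X = g.calls.astype(float)
    X[X == MISSING] = np.nan
    called = ~np.isnan(X)
    if K == 1:
        p = np.nanmean(X, axis=0) / 2.0
        F = np.clip(p, _F_EPS, 1 - _F_EPS)[None, :]
        Q = np.ones((g.n_samples, 1))
        return AncestryModel(1, Q, F, _loglik(X, called, Q, F))

    rng = np.random.default_rng(seed)
    best: AncestryModel | None = None
    for _ in range(n_starts):
        model = _em_once(X, called, K, rng, max_iter, tol)
        if best is None or model.loglik > best.loglik:
            best = model
    assert best is not None
    if not best.converged:
        logger.warning("admixture_fit: EM did not converge in %d iterations", max_iter)
    return best


def _loglik(X, called, Q, F) -> float:
    P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
    with np.errstate(invalid="ignore"):
        ll = X * np.log(P) + (2.0 - X) * np.log(1.0 - P)
    return float(np.nansum(ll))


def _em_once(X, called, K, rng, max_iter, tol) -> AncestryModel:
    n, m = X.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.05, 0.95, size=(K, m)), _F_EPS, 1 - _F_EPS)
    Xz = np.nan_to_num(X)           # missing entries contribute nothing
    X2z = np.nan_to_num(2.0 - X)
    m_called = called.sum(axis=1)

    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
        # responsibilities: a_ijk for the reference allele, b_ijk for the other
        num_a = Xz / P          # n x m
        num_b = X2z / (1.0 - P)
        # E-step sums without materializing n x m x K:
        #   A_ik = sum_j x_ij * q_ik f_kj / p_ij = q_ik * (num_a @ f_k)
        A = Q * (num_a @ F.T)   # n x K
        B = Q * (num_b @ (1.0 - F).T)
        Q_new = (A + B) / (2.0 * m_called)[:, None]
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        #   F numerator: sum_i x_ij q_ik / p_ij ; denominator adds the b-part
        FA = F * (Q.T @ (Xz / P))          # K x m
        FB = (1.0 - F) * (Q.T @ (X2z / (1.0 - P)))
        F_new = np.clip(FA / (FA + FB), _F_EPS, 1 - _F_EPS)

        Q, F = Q_new, F_new
        ll = _loglik(X, called, Q, F)
        if ll < ll_prev - 1e-6 * (abs(ll_prev) + 1.0):
            raise RuntimeError(f"EM log-likelihood decreased at iteration {it}")
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
    return AncestryModel(K, Q, F, ll_prev, converged=converged)


def align_clusters(Q_hat: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute estimated clusters to best match a reference Q (label switching)."""
    from itertools import permutations

    K = Q_hat.shape[1]
    best_perm = min(
        permutations(range(K)),
        key=lambda perm: np.abs(Q_hat[:, list(perm)] - Q_true).mean(),
    )
    return Q_hat[:, list(best_perm)]


def target_lineage_proportion(
    model: AncestryModel, sample_ids: list[str], reference_ids: list[str]
) -> pd.Series:
    """Per-individual proportion of the cluster dominating the reference set.

    The target ancestry (e.g. the indigenous lineage) is identified as the
    Q column with the highest mean over designated reference individuals.
    """
    index = {s: i for i, s in enumerate(sample_ids)}
    ref_rows = [index[s] for s in reference_ids]
    if not ref_rows:
        raise ValueError("no reference individuals found in the sample list")
    k = int(model.Q[ref_rows].mean(axis=0).argmax())
    return pd.Series(model.Q[:, k], index=sample_ids, name="target_proportion")


def classify_lineage(
    proportions: pd.Series, mean: float | None = None, sd: float | None = None
) -> pd.DataFrame:
    """Four-category split of lineage proportions and the nucleus flag.

    Min1: p > mean; Min2: mean-1SD < p <= mean; Min3: mean-2SD < p <=
    mean-1SD; Min4: p <= mean-2SD.  The nucleus conservation population is
    Min1 + Min2 (proportion above mean minus one SD); the rest form the
    candidate population.  Boundaries use strict inequality on the lower
    side of each category.
    """
    mean = float(proportions.mean()) if mean is None else mean
    sd = float(proportions.std(ddof=1)) if sd is None else sd
    if sd <= 0:
        raise ValueError("sd must be positive")
    edges = (mean, mean - sd, mean - 2 * sd)
    cats = []
    for p in proportions:
        if p > edges[0]:
            cats.append("Min1")
        elif p > edges[1]:
            cats.append("Min2")
        elif p > edges[2]:
            cats.append("Min3")
        else:
            cats.append("Min4")
    out = pd.DataFrame(
        {
            "proportion": proportions,
            "category": pd.Categorical(cats, categories=list(MIN_CATEGORIES)),
        },
        index=proportions.index,
    )
    out["nucleus"] = out["category"].isin(("Min1", "Min2"))
    return out
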