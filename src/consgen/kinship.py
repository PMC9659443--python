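"""Pedigree (A), genomic (G) and single-step combined (H) relationship
matrices, and the 1 - r genetic-distance transform.

Entries are numerator-relationship-scale values: a parent-offspring pair is
0.5, self is >= 1.  The family-partition threshold used downstream (0.0625)
and the distance D = 1 - r are applied to these entries directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .plinkio import MISSING, GenotypeMatrix, PedigreeTable

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    ids: list[str]
    values: np.ndarray
    source: str  # one of A, G, H

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        if not np.isfinite(self.values).all():
            raise ValueError("kinship matrix has non-finite entries")
        if self.source not in ("A", "G", "H"):
            raise ValueError("source must be A, G or H")

    def restrict(self, ids: list[str]) -> "KinshipMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        idx = [index[s] for s in ids]
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)], self.source)

    def to_tsv(self) -> str:
        header = "id\t" + "\t".join(self.ids)
        rows = [
            self.ids[i] + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i])
            for i in range(len(self.ids))
        ]
        return header + "\n" + "\n".join(rows) + "\n"


def a_matrix(ped: PedigreeTable) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    A_ii = 1 + 0.5 * A_sire,dam; A_ij = 0.5 * (A_j,sire + A_j,dam) for j
    processed before i; unknown parents contribute zero.
    """
    order = ped.topological_order()
    index = {s: i for i, s in enumerate(order)}
    rec = {r.id: r for r in ped.records}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = rec[ind].sire, rec[ind].dam
        si = index.get(s)
        di = index.get(d)
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        for j in range(i):
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[i, j] = A[j, i] = a
    # report in the pedigree's own record order
    perm = [index[i] for i in ped.ids]
    return KinshipMatrix(list(ped.ids), A[np.ix_(perm, perm)], "A")


def g_matrix(g: GenotypeMatrix, min_maf: float = 0.0) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Z = M - 2p (column-centred 0/1/2 calls, missing mean-imputed per SNP),
    G = Z Z' / (2 * sum_j p_j (1 - p_j)), with in-sample frequencies p_j.
    Monomorphic SNPs (and optionally those below ``min_maf``) are excluded.
    """
    p = g.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    keep = np.isfinite(p) & (maf > min_maf if min_maf > 0 else (p > 0) & (p < 1))
    if not keep.any():
        raise ValueError("no polymorphic SNPs available for the G matrix")
    p = p[keep]
    M = g.calls[:, keep].astype(float)
    miss = M == MISSING
    M[miss] = np.broadcast_to(2 * p, M.shape)[miss]
    Z = M - 2 * p
    denom = 2.0 * np.sum(p * (1 - p))
    G = Z @ Z.T / denom
    G = (G + G.T) / 2.0
    return KinshipMatrix(g.sample_ids, G, "G")


def h_matrix(
    a: KinshipMatrix,
    gmat: KinshipMatrix,
    genotyped_ids: list[str] | None = None,
    blend_w: float = 0.05,
) -> KinshipMatrix:
    """Single-step H matrix combining pedigree and genomic information.

    With A partitioned into non-genotyped (1) and genotyped (2) blocks and
    Gw = (1 - w) G + w A22:

        H22 = Gw
        H12 = A12 A22^-1 Gw
        H11 = A11 + A12 A22^-1 (Gw - A22) A22^-1 A21
    """
    genotyped_ids = list(gmat.ids if genotyped_ids is None else genotyped_ids)
    missing_ids = set(genotyped_ids) - set(a.ids)
    if missing_ids:
        raise ValueError(f"genotyped ids absent from pedigree matrix: {sorted(missing_ids)}")
    if not genotyped_ids:
        return KinshipMatrix(list(a.ids), a.values.copy(), "H")

    gset = set(genotyped_ids)
    ids1 = [i for i in a.ids if i not in gset]
    ids2 = [i for i in a.ids if i in gset]
    index = {s: i for i, s in enumerate(a.ids)}
    i1 = [index[s] for s in ids1]
    i2 = [index[s] for s in ids2]
    A11 = a.values[np.ix_(i1, i1)]
    A12 = a.values[np.ix_(i1, i2)]
    A22 = a.values[np.ix_(i2, i2)]
    G22 = gmat.restrict(ids2).values
    Gw = (1.0 - blend_w) * G22 + blend_w * A22

    if ids1:
        try:
            A22_inv = np.linalg.inv(A22)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "A22 is singular; consider blending (blend_w > 0) or pruning duplicates"
            ) from exc
        T = A12 @ A22_inv
        H11 = A11 + T @ (Gw - A22) @ T.T
        H12 = T @ Gw
        n = len(a.ids)
        H = np.zeros((n, n))
        pos = {s: k for k, s in enumerate(ids1 + ids2)}
        H[: len(ids1), : len(ids1)] = H11
        H[: len(ids1), len(ids1):] = H12
        H[len(ids1):, : len(ids1)] = H12.T
        H[len(ids1):, len(ids1):] = Gw
        order = [pos[s] for s in a.ids]
        H = H[np.ix_(order, order)]
    else:
        H = Gw
    H = (H + H.T) / 2.0
    return KinshipMatrix(list(a.ids), H, "H")


def matrix_correlation(m1: KinshipMatrix, m2: KinshipMatrix) -> tuple[float, float]:
    """Pearson r and two-sided p over strictly-lower-triangle entries."""
    if m1.ids != m2.ids:
        raise ValueError("matrices must share the same id ordering")
    tri = np.tril_indices(len(m1.ids), k=-1)
    x, y = m1.values[tri], m2.values[tri]
    if x.size < 2:
        raise ValueError("need at least two pairs to correlate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def genetic_distance(k: KinshipMatrix) -> np.ndarray:
    """D = 1 - r with a zero diagonal; off-diagonal r > 1 clamps to D = 0."""
    D = 1.0 - k.values
    np.fill_diagonal(D, 0.0)
    neg = D < 0
    if neg.any():
        logger.warning("genetic_distance: %d entries with r > 1 clamped to D=0", int(neg.sum()))
        D[neg] = 0.0
    D = (D + D.T) / 2.0
    return D
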