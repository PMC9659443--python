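"""Family partition of a conserved population by complete-linkage
clustering on genetic distance.

Boars are clustered first: the dendrogram (complete linkage on D = 1 - r)
is cut at height 1 - 0.0625 = 0.9375, so any pair with relationship
r >= 0.0625 (first-cousin level) is forced into the same family.  Every
other individual is then assigned to the family whose boars it is closest
to on average.  The dendrogram can be exported as Newick.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_KINSHIP_THRESHOLD = 0.0625


def _check_distance(d: np.ndarray) -> None:
    d = np.asarray(d)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")


def complete_linkage(d: np.ndarray) -> np.ndarray:
    """Complete-linkage merge table (scipy linkage format)."""
    _check_distance(d)
    return hierarchy.linkage(squareform(np.asarray(d, dtype=float), checks=False), method="complete")


def cluster_boars(
    d: np.ndarray,
    ids: list[str],
    threshold_r: float = DEFAULT_KINSHIP_THRESHOLD,
    n_families: int | None = None,
) -> pd.Series:
    """Family label per boar from complete-linkage clustering.

    The tree is cut at height 1 - ``threshold_r`` (families are the
    clusters below the cut), or at exactly ``n_families`` clusters when
    that is given.  Labels are canonical: family 1 contains the first id.
    """
    if len(ids) < 2:
        logger.warning("cluster_boars: fewer than 2 individuals, single family")
        return pd.Series([1] * len(ids), index=ids, name="family")
    Z = complete_linkage(d)
    if n_families is not None:
        raw = hierarchy.fcluster(Z, t=n_families, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(Z, t=1.0 - threshold_r, criterion="distance")
    return _canonical_labels(raw, ids)


def _canonical_labels(raw: np.ndarray, ids: list[str]) -> pd.Series:
    """Relabel clusters 1..k in order of each cluster's first appearance."""
    mapping: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels.append(mapping[r])
    return pd.Series(labels, index=ids, name="family")


def assign_population(
    d_full: np.ndarray,
    all_ids: list[str],
    boar_families: pd.Series,
) -> pd.Series:
    """Assign every individual to a boar family.

    Boars keep their cluster label; every other individual joins the
    family with the smallest mean distance to that family's boars, ties
    broken toward the smallest family index (and logged).
    """
    _check_distance(d_full)
    index = {s: i for i, s in enumerate(all_ids)}
    fam_rows = {
        fam: [index[b] for b in boar_families.index[boar_families == fam]]
        for fam in sorted(boar_families.unique())
    }
    out = {}
    for ind in all_ids:
        if ind in boar_families.index:
            out[ind] = int(boar_families[ind])
            continue
        i = index[ind]
        means = {fam: float(np.mean([d_full[i, j] for j in rows])) for fam, rows in fam_rows.items()}
        best = min(means.values())
        candidates = [fam for fam, v in means.items() if np.isclose(v, best, atol=1e-12)]
        if len(candidates) > 1:
            logger.info("assign_population: %s equidistant to families %s; chose %d",
                        ind, candidates, candidates[0])
        out[ind] = int(candidates[0])
    return pd.Series([out[s] for s in all_ids], index=all_ids, name="family")


def export_tree(d: np.ndarray, ids: list[str]) -> str:
    """Complete-linkage dendrogram as a Newick string.

    Branch lengths place leaves at height 0 and each internal node at half
    its merge distance (an ultrametric tree): two leaves at distance d
    yield ``(a:h,b:h);`` with h = d/2.
    """
    if len(ids) == 1:
        return f"{ids[0]}:0;"
    Z = complete_linkage(d)
    tree = hierarchy.to_tree(Z)

    def height(node) -> float:
        return node.dist / 2.0

    def walk(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        parts = []
        for child in (node.left, node.right):
            blen = height(node) - (0.0 if child.is_leaf() else height(child))
            parts.append(f"{walk(child)}:{blen:.10g}")
        return "(" + ",".join(parts) + ")"

    return walk(tree) + ";"


def family_table(labels: pd.Series, boar_ids: list[str]) -> pd.DataFrame:
    """Assignment TSV payload: individual, family, is_boar flag."""
    return pd.DataFrame(
        {
            "id": labels.index,
            "family": labels.values,
            "is_boar": [i in set(boar_ids) for i in labels.index],
        }
    )
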