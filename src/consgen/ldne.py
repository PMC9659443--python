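"""Linkage disequilibrium decay and LD-based historical effective
population size.

r^2 is the squared Pearson correlation of unphased 0/1/2 genotype vectors
(composite LD), computed within chromosomes.  Binned mean r^2 at distance
c Morgans is converted to an effective size with the drift expectation

    Ne = (1 / 4c) * (1 / r^2 - 1)

and each bin is mapped to a time depth t generations ago; the default map
is t = 1/(2c), with the published six-bin preset available as
``paper2022``.  Physical distance converts to map distance at 1 cM per Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .plinkio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Upper bin edges (kb): 0.5, 1, 2, 5, 10 and 100 Mb.
DEFAULT_BIN_EDGES_KB = (500.0, 1000.0, 2000.0, 5000.0, 10000.0, 100000.0)

#: Published mapping of the six default bins to generation depths
#: (200, 50, 20, 10, 5 generations ago and the current generation).
PAPER2022_GENERATIONS = (200.0, 50.0, 20.0, 10.0, 5.0, 0.0)


@dataclass
class LDBin:
    min_kb: float
    max_kb: float
    mean_r2: float
    n_pairs: int

    @property
    def c_morgan(self) -> float:
        """Midpoint distance in Morgans (1 cM per Mb, so 1 Mb = 0.01 M)."""
        mid_kb = (self.min_kb + self.max_kb) / 2.0
        return mid_kb / 1e3 / 100.0


@dataclass
class NeEstimate:
    generations_ago: float
    ne: float


def pairwise_r2(
    g: GenotypeMatrix, max_dist_kb: float = 1e5
) -> Iterator[tuple[float, float]]:
    """Yield (distance_kb, r2) for within-chromosome SNP pairs.

    r2 is computed over samples called at both sites; monomorphic pairs
    are skipped.
    """
    chroms = g.chromosomes()
    pos = g.positions()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        calls = g.calls[:, idx].astype(float)
        calls[calls == MISSING] = np.nan
        p = pos[idx]
        m = idx.size
        for a in range(m):
            for b in range(a + 1, m):
                d_kb = (p[b] - p[a]) / 1e3
                if d_kb > max_dist_kb:
                    break
                r2 = _r2_pair(calls[:, a], calls[:, b])
                if r2 is not None:
                    yield d_kb, r2


def _r2_pair(x: np.ndarray, y: np.ndarray) -> float | None:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return None
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return None
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def bin_ld(
    g: GenotypeMatrix,
    bin_edges_kb: tuple[float, ...] = DEFAULT_BIN_EDGES_KB,
    sample_size_adjust: bool = False,
) -> list[LDBin]:
    """Mean r^2 per inter-SNP distance bin (vectorized per chromosome).

    Bins are (prev_edge, edge] intervals starting at 0.  With
    ``sample_size_adjust`` the finite-sample term 1/n is subtracted from
    each pair's r^2 (default off).
    """
    edges = np.asarray(bin_edges_kb, dtype=float)
    sums = np.zeros(edges.size)
    counts = np.zeros(edges.size, dtype=np.int64)
    chroms = g.chromosomes()
    pos = g.positions()
    n = g.n_samples
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < 2:
            continue
        calls = g.calls[:, idx].astype(float)
        calls[calls == MISSING] = np.nan
        # correlation matrix over pairwise-complete observations
        R = _nan_corrcoef(calls)
        p = pos[idx]
        iu = np.triu_indices(idx.size, k=1)
        d_kb = (p[iu[1]] - p[iu[0]]) / 1e3
        r2 = R[iu] ** 2
        ok = np.isfinite(r2)
        if sample_size_adjust:
            r2 = r2 - 1.0 / n
        which = np.searchsorted(edges, d_kb[ok], side="left")
        inside = which < edges.size
        np.add.at(sums, which[inside], r2[ok][inside])
        np.add.at(counts, which[inside], 1)
    bins = []
    prev = 0.0
    for e, s, c in zip(edges, sums, counts):
        if c > 0:
            bins.append(LDBin(min_kb=prev, max_kb=float(e), mean_r2=float(s / c), n_pairs=int(c)))
        else:
            logger.info("bin_ld: empty bin (%g, %g] kb omitted", prev, e)
        prev = float(e)
    return bins


def _nan_corrcoef(calls: np.ndarray) -> np.ndarray:
    """Column correlation matrix using pairwise-complete samples."""
    mask = ~np.isnan(calls)
    X = np.nan_to_num(calls)
    n_ab = mask.T.astype(float) @ mask.astype(float)
    s_ab = X.T @ X
    sum_a = X.T @ mask.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = sum_a / n_ab
        cov = s_ab / n_ab - mean_a * mean_a.T
        sq_a = (X**2).T @ mask.astype(float)
        var1 = sq_a / n_ab - mean_a**2
        var2 = var1.T
        R = cov / np.sqrt(var1 * var2)
    R[~np.isfinite(R)] = np.nan
    return R


def ne_estimate(mean_r2: float, c_morgan: float) -> float:
    """Effective size from the drift expectation: Ne = (1/4c)(1/r^2 - 1)."""
    if not (0.0 < mean_r2 <= 1.0):
        raise ValueError("mean_r2 must be in (0, 1]")
    if c_morgan <= 0:
        raise ValueError("c_morgan must be positive")
    return (1.0 / (4.0 * c_morgan)) * (1.0 / mean_r2 - 1.0)


def ne_trajectory(
    bins: list[LDBin], mapping: str = "halfc"
) -> list[NeEstimate]:
    """One Ne estimate per LD bin with a generation depth for each.

    ``mapping='halfc'`` uses t = 1/(2c); ``mapping='paper2022'`` uses the
    published six-bin depths (requires the default bins).
    """
    out = []
    if mapping == "paper2022":
        gen_by_max = dict(zip(DEFAULT_BIN_EDGES_KB, PAPER2022_GENERATIONS))
        for b in bins:
            if b.max_kb not in gen_by_max:
                raise ValueError(
                    f"paper2022 mapping needs the default bins; got edge {b.max_kb}"
                )
            out.append(NeEstimate(gen_by_max[b.max_kb], ne_estimate(b.mean_r2, b.c_morgan)))
    elif mapping == "halfc":
        for b in bins:
            out.append(NeEstimate(1.0 / (2.0 * b.c_morgan), ne_estimate(b.mean_r2, b.c_morgan)))
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return out
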