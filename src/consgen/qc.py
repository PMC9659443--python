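"""Genotype quality control and diversity statistics.

The QC pipeline applies five criteria sequentially, each measured on the
survivors of the previous step: (i) keep autosomal SNPs, (ii) drop samples
with call rate < 0.90, (iii) drop SNPs with call rate < 0.90, (iv) drop
SNPs with MAF < 0.01, (v) drop SNPs with Hardy-Weinberg exact p < 1e-6.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .plinkio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_input_snps: int = 0
    n_autosomal: int = 0
    n_removed_sample_callrate: int = 0
    n_removed_snp_callrate: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        """Sequential-filter bookkeeping: survivors of the SNP filters."""
        return (
            self.n_autosomal
            - self.n_removed_snp_callrate
            - self.n_removed_maf
            - self.n_removed_hwe
        )

    def to_tsv(self) -> str:
        rows = [
            ("input_snps", self.n_input_snps),
            ("autosomal", self.n_autosomal),
            ("removed_samples_callrate", self.n_removed_sample_callrate),
            ("removed_snps_callrate", self.n_removed_snp_callrate),
            ("removed_snps_maf", self.n_removed_maf),
            ("removed_snps_hwe", self.n_removed_hwe),
            ("retained", self.n_retained),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


@dataclass
class DiversityStats:
    mean_maf: float
    pn: float
    ho: float
    he: float
    maf_histogram: np.ndarray  # counts per 0.05-wide MAF bin, [0,0.05)..[0.45,0.5]

    def to_tsv(self) -> str:
        rows = [
            ("mean_maf", f"{self.mean_maf:.6f}"),
            ("pn", f"{self.pn:.6f}"),
            ("ho", f"{self.ho:.6f}"),
            ("he", f"{self.he:.6f}"),
        ]
        for b, count in enumerate(self.maf_histogram):
            rows.append((f"maf_bin_{0.05 * b:.2f}_{0.05 * (b + 1):.2f}", str(int(count))))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, whose probability does not exceed that of the
    observed table (no mid-p adjustment).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        warnings.warn("HWE test on zero genotypes is undefined; returning 1")
        return 1.0
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    probs = _het_count_distribution(n, n_rare)
    p_obs = probs.get(n_Aa, 0.0)
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))
    return min(1.0, p)


def _het_count_distribution(n: int, n_rare: int) -> dict[int, float]:
    """P(het count) for all feasible tables with the given allele totals.

    Uses the standard recurrence on the conditional distribution of the
    heterozygote count; het counts share the parity of the rare-allele count.
    """
    het0 = n_rare % 2
    hets = list(range(het0, min(n_rare, 2 * n - n_rare) + 1, 2))
    # unnormalized weights via the two-step recurrence, in log space
    logw = {hets[0]: 0.0}
    for h in hets[1:]:
        # moving h-2 -> h converts one hom-rare + one hom-common into two hets
        prev = logw[h - 2]
        hom_r = (n_rare - (h - 2)) // 2
        hom_c = n - (h - 2) - hom_r
        logw[h] = prev + np.log(4.0 * hom_r * hom_c) - np.log(h * (h - 1))
    mx = max(logw.values())
    w = {h: np.exp(v - mx) for h, v in logw.items()}
    total = sum(w.values())
    return {h: v / total for h, v in w.items()}


def _snp_call_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP counts of (hom a1, het, hom a2) over non-missing calls."""
    c = g.calls
    return (c == 2).sum(axis=0), (c == 1).sum(axis=0), (c == 0).sum(axis=0)


def snp_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing calls (NaN if no calls)."""
    p = g.allele_frequencies()
    return np.minimum(p, 1.0 - p)


def apply_qc(
    g: GenotypeMatrix,
    sample_cr: float = 0.90,
    snp_cr: float = 0.90,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the five QC criteria in order; returns survivors and a report."""
    report = QCReport(n_input_snps=g.n_variants)

    g = g.autosomal()
    report.n_autosomal = g.n_variants

    call_rate_sample = (g.calls != MISSING).mean(axis=1)
    keep_s = np.flatnonzero(call_rate_sample >= sample_cr)
    report.removed_sample_ids = [
        g.samples[i].id for i in np.flatnonzero(call_rate_sample < sample_cr)
    ]
    report.n_removed_sample_callrate = g.n_samples - keep_s.size
    if keep_s.size == 0:
        raise ValueError("all samples removed by the call-rate filter")
    g = g.subset(sample_idx=keep_s)

    call_rate_snp = (g.calls != MISSING).mean(axis=0)
    keep_v = np.flatnonzero(call_rate_snp >= snp_cr)
    report.n_removed_snp_callrate = g.n_variants - keep_v.size
    g = g.subset(variant_idx=keep_v)

    maf = snp_maf(g)
    keep_v = np.flatnonzero(~(np.nan_to_num(maf) < maf_min))
    report.n_removed_maf = g.n_variants - keep_v.size
    g = g.subset(variant_idx=keep_v)

    n2, n1, n0 = _snp_call_counts(g)
    pvals = np.array(
        [hwe_exact_p(int(a), int(b), int(c)) for a, b, c in zip(n2, n1, n0)]
    )
    keep_v = np.flatnonzero(pvals >= hwe_p_min)
    report.n_removed_hwe = g.n_variants - keep_v.size
    g = g.subset(variant_idx=keep_v)

    return g, report


def diversity_stats(
    g: GenotypeMatrix, polymorphism_maf: float = 0.01
) -> DiversityStats:
    """SNP-averaged MAF, polymorphic-marker ratio PN, Ho and He.

    Per SNP j over non-missing calls: Ho_j = #het/#called, He_j = 2*p*(1-p)
    (no small-sample correction, matching PLINK's E(HET)).  Reported values
    are means over SNPs with at least one call; PN is the fraction of SNPs
    with MAF >= ``polymorphism_maf``.
    """
    n2, n1, n0 = _snp_call_counts(g)
    called = n2 + n1 + n0
    ok = called > 0
    n_zero = int((~ok).sum())
    if n_zero:
        logger.info("diversity_stats: %d SNPs with zero calls excluded", n_zero)
    if not ok.any():
        raise ValueError("no SNP has any genotype call")

    p = (2 * n2[ok] + n1[ok]) / (2 * called[ok])
    maf = np.minimum(p, 1 - p)
    ho = n1[ok] / called[ok]
    he = 2 * p * (1 - p)
    hist, _ = np.histogram(maf, bins=np.linspace(0.0, 0.5, 11))
    return DiversityStats(
        mean_maf=float(maf.mean()),
        pn=float((maf >= polymorphism_maf).mean()),
        ho=float(ho.mean()),
        he=float(he.mean()),
        maf_histogram=hist,
    )
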