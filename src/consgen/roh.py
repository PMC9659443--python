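"""Runs-of-homozygosity detection and summaries.

The detector follows the PLINK ``--homozyg`` sliding-window design: a
50-SNP window passes if it holds at most one heterozygous and at most one
missing call; a SNP is ROH-eligible when the fraction of passing windows
overlapping it reaches ``window_hit_threshold``; maximal runs of eligible
SNPs become segments, subject to run-level constraints (minimum SNP count,
minimum length, marker density, maximum inter-SNP gap, and the same
het/missing allowance applied to the whole run).

Segment coordinates are 1-based inclusive; length = end - start + 1 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plinkio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Total autosomal map length (kb) used as the F_ROH denominator by default.
DEFAULT_L_AUTO_KB = 2_450_462.292

CLASS_LABELS = ("1-5 Mb", "5-10 Mb", ">10 Mb")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1e3

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class ROHParams:
    window_snp: int = 50
    min_snp: int = 30
    min_density_kb_per_snp: float = 1000.0
    max_missing_per_window: int = 1
    max_het_per_window: int = 1
    window_hit_threshold: float = 0.05
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("window_snp", "min_snp", "min_density_kb_per_snp",
                     "min_length_kb", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHClassSummary:
    class_label: str
    n_segments: int
    pct_of_segments: float
    mean_length_mb: float
    sd_length_mb: float
    genome_coverage_pct: float


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH per sample on each autosome of a position-sorted panel."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    chroms = g.chromosomes()
    positions = g.positions()
    for chrom in sorted(set(chroms), key=lambda c: (not c.isdigit(), int(c) if c.isdigit() else 0, c)):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"chromosome {chrom}: positions not sorted")
        if idx.size < params.window_snp:
            logger.info("chromosome %s: fewer than %d SNPs, skipped", chrom, params.window_snp)
            continue
        calls = g.calls[:, idx]
        for i, sample in enumerate(g.samples):
            segments.extend(
                _detect_one(sample.id, chrom, pos, calls[i], params)
            )
    return segments


def _detect_one(
    sample_id: str, chrom: str, pos: np.ndarray, row: np.ndarray, params: ROHParams
) -> list[ROHSegment]:
    het = (row == 1).astype(np.int64)
    miss = (row == MISSING).astype(np.int64)
    w = params.window_snp
    m = row.size
    n_windows = m - w + 1

    het_in_window = np.convolve(het, np.ones(w, dtype=np.int64), mode="valid")
    miss_in_window = np.convolve(miss, np.ones(w, dtype=np.int64), mode="valid")
    window_ok = (
        (het_in_window <= params.max_het_per_window)
        & (miss_in_window <= params.max_missing_per_window)
    ).astype(np.int64)

    # SNP j overlaps windows starting in [j-w+1, j], clipped to the chromosome
    ok_cum = np.concatenate(([0], np.cumsum(window_ok)))
    starts = np.maximum(np.arange(m) - w + 1, 0)
    ends = np.minimum(np.arange(m), n_windows - 1)
    hits = ok_cum[ends + 1] - ok_cum[starts]
    n_overlapping = ends - starts + 1
    eligible = hits / n_overlapping >= params.window_hit_threshold

    out: list[ROHSegment] = []
    for a, b in _runs(eligible):
        for s, e in _split_run(pos, het, miss, a, b, params):
            n_snps = e - s + 1
            length_kb = (pos[e] - pos[s] + 1) / 1e3
            if n_snps < params.min_snp:
                continue
            if length_kb < params.min_length_kb:
                continue
            if length_kb / n_snps > params.min_density_kb_per_snp:
                continue
            out.append(
                ROHSegment(sample_id, chrom, int(pos[s]), int(pos[e]), n_snps)
            )
    return out


def _runs(mask: np.ndarray):
    """Maximal runs of True as (first, last) index pairs."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return zip(starts, ends)


def _split_run(pos, het, miss, a, b, params: ROHParams):
    """Split an eligible run at large gaps and at het/missing excess, then
    trim each piece to homozygous called endpoints."""
    pieces = []
    start = a
    for j in range(a + 1, b + 1):
        if (pos[j] - pos[j - 1]) / 1e3 > params.max_gap_kb:
            pieces.append((start, j - 1))
            start = j
    pieces.append((start, b))

    refined = []
    for s0, e0 in pieces:
        s = s0
        n_het = n_miss = 0
        for j in range(s0, e0 + 1):
            over = (
                n_het + het[j] > params.max_het_per_window
                or n_miss + miss[j] > params.max_missing_per_window
            )
            if over:
                refined.append((s, j - 1))
                s = j
                n_het, n_miss = int(het[j]), int(miss[j])
            else:
                n_het += int(het[j])
                n_miss += int(miss[j])
        refined.append((s, e0))

    for s, e in refined:
        while s <= e and (het[s] or miss[s]):
            s += 1
        while e >= s and (het[e] or miss[e]):
            e -= 1
        if s <= e:
            yield s, e


def classify_roh(segments: list[ROHSegment]) -> list[str | None]:
    """Class label per segment: [1,5) / [5,10) / >=10 Mb; <1 Mb unclassified."""
    labels: list[str | None] = []
    for seg in segments:
        mb = seg.length_mb
        if mb < 1.0:
            labels.append(None)
        elif mb < 5.0:
            labels.append(CLASS_LABELS[0])
        elif mb < 10.0:
            labels.append(CLASS_LABELS[1])
        else:
            labels.append(CLASS_LABELS[2])
    return labels


def roh_summary(
    segments: list[ROHSegment],
    n_samples: int,
    l_auto_kb: float = DEFAULT_L_AUTO_KB,
) -> list[ROHClassSummary]:
    """Per-length-class descriptive statistics plus a 'total' row.

    Genome coverage is the summed segment length divided by the population's
    total autosomal map (n_samples * l_auto_kb), as a percentage.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    labels = classify_roh(segments)
    classified = [(seg, lab) for seg, lab in zip(segments, labels) if lab is not None]
    total = len(classified)
    out = []
    for label in CLASS_LABELS + ("total",):
        lens = np.array(
            [s.length_mb for s, lab in classified if label in (lab, "total")]
        )
        n = lens.size
        out.append(
            ROHClassSummary(
                class_label=label,
                n_segments=n,
                pct_of_segments=100.0 * n / total if total else 0.0,
                mean_length_mb=float(lens.mean()) if n else 0.0,
                sd_length_mb=float(lens.std(ddof=1)) if n > 1 else 0.0,
                genome_coverage_pct=100.0 * lens.sum() * 1e3 / (n_samples * l_auto_kb),
            )
        )
    return out


def summary_from_class_counts(
    counts: dict[str, int],
    mean_lengths_mb: dict[str, float],
    n_samples: int,
    l_auto_kb: float = DEFAULT_L_AUTO_KB,
) -> list[ROHClassSummary]:
    """Rebuild class summaries from aggregate counts and mean lengths.

    Useful for checking the internal consistency of published summary
    tables: coverage and the overall mean depend on counts and means only.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    total = sum(counts.values())
    out = []
    for label in CLASS_LABELS:
        n = counts[label]
        tot_mb = n * mean_lengths_mb[label]
        out.append(
            ROHClassSummary(
                class_label=label,
                n_segments=n,
                pct_of_segments=100.0 * n / total,
                mean_length_mb=mean_lengths_mb[label],
                sd_length_mb=float("nan"),
                genome_coverage_pct=100.0 * tot_mb * 1e3 / (n_samples * l_auto_kb),
            )
        )
    grand_mb = sum(counts[c] * mean_lengths_mb[c] for c in CLASS_LABELS)
    out.append(
        ROHClassSummary(
            class_label="total",
            n_segments=total,
            pct_of_segments=100.0,
            mean_length_mb=grand_mb / total,
            sd_length_mb=float("nan"),
            genome_coverage_pct=100.0 * grand_mb * 1e3 / (n_samples * l_auto_kb),
        )
    )
    return out


def per_chromosome_summary(
    segments: list[ROHSegment], variants, n_samples: int
) -> pd.DataFrame:
    """Segment count and % coverage per chromosome.

    The coverage denominator is the chromosome span (first to last marker)
    times ``n_samples``; ``variants`` is any iterable of Variant.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    spans: dict[str, tuple[int, int]] = {}
    for v in variants:
        lo, hi = spans.get(v.chrom, (v.pos_bp, v.pos_bp))
        spans[v.chrom] = (min(lo, v.pos_bp), max(hi, v.pos_bp))
    rows = []
    for chrom, (lo, hi) in sorted(
        spans.items(), key=lambda kv: (not kv[0].isdigit(), int(kv[0]) if kv[0].isdigit() else 0, kv[0])
    ):
        segs = [s for s in segments if s.chrom == chrom]
        span_bp = hi - lo + 1
        cov = 100.0 * sum(s.length_bp for s in segs) / (n_samples * span_bp)
        rows.append({"chrom": chrom, "n_segments": len(segs), "coverage_pct": cov})
    return pd.DataFrame(rows)


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """PLINK .hom-style table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "IID": [s.sample_id for s in segments],
            "CHR": [s.chrom for s in segments],
            "POS1": [s.start_bp for s in segments],
            "POS2": [s.end_bp for s in segments],
            "NSNP": [s.n_snps for s in segments],
            "KB": [s.length_kb for s in segments],
        }
    )


def segments_to_bed(segments: list[ROHSegment]) -> str:
    """BED (0-based half-open) export: start-1, end."""
    lines = [
        f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}" for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
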