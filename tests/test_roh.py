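import numpy as np
import pytest

from consgen.plinkio import MISSING
from consgen.roh import (
    ROHParams,
    ROHSegment,
    classify_roh,
    detect_roh,
    per_chromosome_summary,
    roh_summary,
    segments_to_bed,
    summary_from_class_counts,
)

from conftest import brute_force_roh, make_matrix

STRICT = ROHParams(
    window_snp=50,
    min_snp=50,
    min_density_kb_per_snp=1e9,
    max_missing_per_window=0,
    max_het_per_window=0,
    window_hit_threshold=1e-9,
    min_length_kb=1e-9,
    max_gap_kb=1e12,
)


def test_constructed_positive_tract():
    """40 consecutive homozygous SNPs spanning 2 Mb, flanked by hets."""
    m = 60
    calls = np.ones((1, m), dtype=np.int8)
    calls[0, 10:50] = 2
    g = make_matrix(calls, spacing_bp=50_000)  # 50 kb/SNP density
    params = ROHParams(window_snp=20, min_snp=30, min_length_kb=1000)
    segs = detect_roh(g, params)
    assert len(segs) == 1
    assert segs[0].n_snps == 40
    assert segs[0].start_bp == g.variants[10].pos_bp
    assert segs[0].end_bp == g.variants[49].pos_bp


def test_all_heterozygous_yields_nothing():
    g = make_matrix(np.ones((3, 200), dtype=np.int8), spacing_bp=50_000)
    assert detect_roh(g) == []


def test_unsorted_positions_rejected():
    g = make_matrix(np.zeros((1, 60), dtype=np.int8))
    g.variants[5], g.variants[6] = g.variants[6], g.variants[5]
    with pytest.raises(ValueError, match="sorted"):
        detect_roh(g)


def test_short_chromosome_skipped():
    g = make_matrix(np.full((1, 10), 2, dtype=np.int8))
    assert detect_roh(g, ROHParams()) == []


def test_windowed_detector_equals_brute_force_scanner():
    """With strict parameters (no het/missing tolerance, any-hit window
    rule) the sliding-window detector must equal a maximal-run scanner."""
    rng = np.random.default_rng(21)
    for rep in range(30):
        m = 500
        calls = rng.choice([0, 1, 2], size=(1, m), p=[0.25, 0.5, 0.25]).astype(np.int8)
        # implant two clean homozygous tracts
        for lo in (int(rng.integers(0, 150)), int(rng.integers(250, 400))):
            ln = int(rng.integers(50, 90))
            calls[0, lo : lo + ln] = 2
        g = make_matrix(calls, spacing_bp=40_000)
        segs = detect_roh(g, STRICT)
        oracle = brute_force_roh(
            g.positions(), calls[0], min_snp=STRICT.window_snp,
            min_length_kb=STRICT.min_length_kb,
            min_density_kb_per_snp=STRICT.min_density_kb_per_snp,
        )
        got = [(s.start_bp, s.end_bp, s.n_snps) for s in segs]
        assert got == oracle, f"replicate {rep}"


def test_emitted_segments_satisfy_printed_criteria():
    """Post-hoc check, independent of the detector: every segment has >=
    min_snp SNPs, density at least one SNP per 1000 kb, and at most one
    het and one missing call inside."""
    rng = np.random.default_rng(22)
    calls = rng.choice([0, 1, 2, MISSING], size=(5, 600), p=[0.3, 0.35, 0.3, 0.05]).astype(np.int8)
    for i in range(5):
        lo = int(rng.integers(0, 500))
        calls[i, lo : lo + 80] = 2
        # sprinkle an allowed het inside
        calls[i, lo + 40] = 1
    g = make_matrix(calls, spacing_bp=40_000)
    params = ROHParams(min_length_kb=1000)
    segs = detect_roh(g, params)
    assert segs, "expected at least one segment"
    ids = {s.id: k for k, s in enumerate(g.samples)}
    pos = g.positions()
    for s in segs:
        assert s.n_snps >= params.min_snp
        assert s.length_kb / s.n_snps <= params.min_density_kb_per_snp
        inside = (pos >= s.start_bp) & (pos <= s.end_bp)
        row = g.calls[ids[s.sample_id], inside]
        assert (row == 1).sum() <= params.max_het_per_window
        assert (row == MISSING).sum() <= params.max_missing_per_window


def test_sample_order_invariance():
    rng = np.random.default_rng(23)
    calls = rng.choice([0, 1, 2], size=(4, 300), p=[0.3, 0.4, 0.3]).astype(np.int8)
    calls[:, 100:180] = 2
    g = make_matrix(calls, spacing_bp=40_000)
    rev = g.subset(sample_idx=[3, 2, 1, 0])
    def key(segs):
        return sorted((s.sample_id, s.start_bp, s.end_bp) for s in segs)
    assert key(detect_roh(g)) == key(detect_roh(rev))


class TestClassification:
    def test_boundaries(self):
        segs = [
            ROHSegment("a", "1", 1, int(3.48e6), 40),
            ROHSegment("a", "1", 1, int(10.0e6), 40),
            ROHSegment("a", "1", 1, int(0.8e6), 40),
            ROHSegment("a", "1", 1, int(5.0e6), 40),
        ]
        assert classify_roh(segs) == ["1-5 Mb", ">10 Mb", None, "5-10 Mb"]


class TestSummaries:
    def test_single_full_coverage_sample(self):
        l_auto_kb = 2000.0
        seg = ROHSegment("a", "1", 1, int(l_auto_kb * 1e3), 100)
        rows = roh_summary([seg], n_samples=4, l_auto_kb=l_auto_kb)
        total = rows[-1]
        assert total.genome_coverage_pct == pytest.approx(100.0 / 4)

    def test_matches_hand_aggregation(self):
        rng = np.random.default_rng(31)
        segs = [
            ROHSegment("a", "1", 1, int(rng.uniform(1.2, 30) * 1e6), 50)
            for _ in range(40)
        ]
        rows = roh_summary(segs, n_samples=10, l_auto_kb=2_450_462.292)
        lens = np.array([s.length_mb for s in segs])
        by_class = {
            "1-5 Mb": lens[(lens >= 1) & (lens < 5)],
            "5-10 Mb": lens[(lens >= 5) & (lens < 10)],
            ">10 Mb": lens[lens >= 10],
            "total": lens,
        }
        for row in rows:
            ref = by_class[row.class_label]
            assert row.n_segments == ref.size
            assert row.mean_length_mb == pytest.approx(ref.mean())
            assert row.genome_coverage_pct == pytest.approx(
                100 * ref.sum() * 1e3 / (10 * 2_450_462.292)
            )
        assert sum(r.n_segments for r in rows[:3]) == rows[-1].n_segments

    def test_aggregate_rebuild_equals_full_summary(self):
        """summary_from_class_counts reproduces coverage and the overall
        mean computed from raw segments."""
        segs = [
            ROHSegment("a", "1", 1, int(2.0e6), 50),
            ROHSegment("a", "1", 1, int(4.0e6), 50),
            ROHSegment("b", "1", 1, int(7.0e6), 50),
            ROHSegment("b", "1", 1, int(12.0e6), 50),
        ]
        full = roh_summary(segs, n_samples=2, l_auto_kb=30_000.0)
        rebuilt = summary_from_class_counts(
            {"1-5 Mb": 2, "5-10 Mb": 1, ">10 Mb": 1},
            {"1-5 Mb": 3.0, "5-10 Mb": 7.0, ">10 Mb": 12.0},
            n_samples=2,
            l_auto_kb=30_000.0,
        )
        for a, b in zip(full, rebuilt):
            assert a.genome_coverage_pct == pytest.approx(b.genome_coverage_pct)
            assert a.mean_length_mb == pytest.approx(b.mean_length_mb)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            roh_summary([], n_samples=0)


class TestPerChromosome:
    def test_empty_and_full_chromosomes(self):
        g = make_matrix(np.zeros((2, 10), dtype=np.int8), spacing_bp=100_000)
        span = g.variants[-1].pos_bp - g.variants[0].pos_bp + 1
        segs = [
            ROHSegment(s, "1", g.variants[0].pos_bp, g.variants[-1].pos_bp, 10)
            for s in ("s1", "s2")
        ]
        tab = per_chromosome_summary(segs, g.variants, n_samples=2)
        assert tab.loc[0, "n_segments"] == 2
        assert tab.loc[0, "coverage_pct"] == pytest.approx(100.0)
        empty = per_chromosome_summary([], g.variants, n_samples=2)
        assert empty.loc[0, "n_segments"] == 0
        assert empty.loc[0, "coverage_pct"] == 0.0


def test_bed_export_is_zero_based_half_open():
    seg = ROHSegment("a", "3", 1001, 2000, 30)
    assert segments_to_bed([seg]) == "3\t1000\t2000\ta\n"
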