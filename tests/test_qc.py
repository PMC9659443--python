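import math

import numpy as np
import pytest

from consgen.plinkio import MISSING, GenotypeMatrix, SampleRecord, Variant
from consgen.qc import apply_qc, diversity_stats, hwe_exact_p

from conftest import make_matrix


def hwe_enumeration(n_AA, n_Aa, n_aa):
    """Independent oracle: exhaustive enumeration of all het counts with the
    observed allele totals, weighted by the exact conditional probability."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    logs = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logs[h] = (
            math.lgamma(n + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_c + 1)
            + h * math.log(2)
        )
    mx = max(logs.values())
    w = {h: math.exp(v - mx) for h, v in logs.items()}
    tot = sum(w.values())
    probs = {h: v / tot for h, v in w.items()}
    p_obs = probs.get(n_Aa, 0.0)
    return min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)))


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 0, 0), 1.0), ((0, 1, 0), 1.0), ((0, 5, 0), None), ((14, 57, 29), None)],
    )
    def test_matches_enumeration(self, counts, expected):
        p = hwe_exact_p(*counts)
        if expected is not None:
            assert p == pytest.approx(expected)
        assert p == pytest.approx(hwe_enumeration(*counts), abs=1e-10)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            n_AA = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_AA + 1))
            n_aa = n - n_AA - n_Aa
            assert hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
                hwe_enumeration(n_AA, n_Aa, n_aa), abs=1e-10
            )

    def test_zero_counts_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert hwe_exact_p(0, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 0)


def _planted_panel():
    """30 samples x 23 SNPs with one violation per filter step.

    Column 0 is on X (dropped as non-autosomal); column 1 is missing in 9
    survivors (call rate ~0.69); column 2 is monomorphic; column 3 is all
    heterozygous (gross HWE departure); the rest are clean HWE draws.  The
    last sample is missing at every autosomal SNP.
    """
    rng = np.random.default_rng(5)
    n, m = 30, 23
    calls = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
    calls[:9, 1] = MISSING
    calls[:, 2] = 2
    calls[:, 3] = 1
    calls[n - 1, 1:] = MISSING
    samples = [SampleRecord(id=f"s{i + 1}") for i in range(n)]
    variants = [Variant("vX", "X", 50)] + [
        Variant(f"v{j + 1}", "1", 100 * (j + 1), "A", "B") for j in range(1, m)
    ]
    return GenotypeMatrix(samples, variants, calls)


class TestApplyQC:
    def test_sequential_counts_match_recount(self):
        g = _planted_panel()
        out, report = apply_qc(g)
        assert report.n_input_snps == 23
        assert report.n_autosomal == 22
        assert report.removed_sample_ids == ["s30"]
        assert report.n_removed_sample_callrate == 1
        # on the 29 survivors: column 1 called in 20/29 -> rate 0.69 < 0.9
        assert report.n_removed_snp_callrate == 1
        assert report.n_removed_maf == 1  # monomorphic column
        assert report.n_removed_hwe == 1  # all-het column
        assert report.n_retained == 19
        assert out.n_variants == 19
        assert report.n_retained == (
            report.n_autosomal
            - report.n_removed_snp_callrate
            - report.n_removed_maf
            - report.n_removed_hwe
        )

    def test_low_callrate_snp_removed(self):
        calls = np.ones((10, 10), dtype=np.int8)
        calls[:2, 0] = MISSING  # genotyped in 8/10; samples keep rate 0.9
        g = make_matrix(calls)
        _, report = apply_qc(g)
        assert report.n_removed_snp_callrate == 1

    def test_monomorphic_removed_at_maf_step(self):
        g = make_matrix(np.full((10, 1), 2, dtype=np.int8))
        _, report = apply_qc(g)
        assert report.n_removed_maf == 1

    def test_all_samples_removed_is_error(self):
        g = make_matrix(np.full((3, 2), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="all samples"):
            apply_qc(g)


class TestDiversityStats:
    def test_all_het(self):
        g = make_matrix(np.ones((6, 4), dtype=np.int8))
        s = diversity_stats(g)
        assert s.ho == 1.0
        assert s.he == pytest.approx(0.5)
        assert s.mean_maf == pytest.approx(0.5)

    def test_fixed_snp(self):
        g = make_matrix(np.full((6, 1), 2, dtype=np.int8))
        s = diversity_stats(g)
        assert s.ho == s.he == 0.0
        assert s.pn == 0.0

    def test_matches_per_site_enumeration(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2, MISSING], size=(20, 200), p=[0.3, 0.3, 0.3, 0.1])
        g = make_matrix(calls.astype(np.int8))
        s = diversity_stats(g)
        hos, hes, mafs = [], [], []
        for j in range(200):
            col = calls[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            p = obs.sum() / (2 * obs.size)
            hos.append(np.mean(obs == 1))
            hes.append(2 * p * (1 - p))
            mafs.append(min(p, 1 - p))
        assert s.ho == pytest.approx(np.mean(hos))
        assert s.he == pytest.approx(np.mean(hes))
        assert s.mean_maf == pytest.approx(np.mean(mafs))

    def test_ho_approaches_he_under_hwe(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, size=300)
        calls = rng.binomial(2, np.broadcast_to(p, (10_000, 300))).astype(np.int8)
        s = diversity_stats(make_matrix(calls))
        assert s.ho == pytest.approx(s.he, abs=0.01)

    def test_histogram_has_ten_bins_summing_to_snps(self, toy_matrix):
        s = diversity_stats(toy_matrix)
        assert s.maf_histogram.size == 10
        assert s.maf_histogram.sum() == toy_matrix.n_variants
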