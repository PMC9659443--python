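import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from consgen.plinkio import (
    MISSING,
    GenotypeMatrix,
    PedigreeError,
    PedigreeTable,
    PlinkFormatError,
    SampleRecord,
    TriallelicError,
    Variant,
    intersect_panels,
    read_plink_binary,
    read_plink_text,
    write_plink_binary,
    write_plink_text,
)

from conftest import make_matrix


def _write_toy_text(tmp_path, ped_rows, map_rows):
    ped = tmp_path / "t.ped"
    map_ = tmp_path / "t.map"
    ped.write_text("\n".join(ped_rows) + "\n")
    map_.write_text("\n".join(map_rows) + "\n")
    return ped, map_


class TestPlinkText:
    def test_recoding_hom_het_missing(self, tmp_path):
        ped, map_ = _write_toy_text(
            tmp_path,
            [
                "F 1 0 0 1 -9 A A C C",
                "F 2 0 0 2 -9 A G 0 0",
                "F 3 0 0 0 -9 G G C T",
            ],
            ["1 snp1 0 1000", "1 snp2 0 2000"],
        )
        g = read_plink_text(ped, map_)
        # snp1: first call is hom A -> a1=A; snp2: first call hom C -> a1=C
        assert g.calls[0, 0] == 2  # A A
        assert g.calls[1, 0] == 1  # A G
        assert g.calls[2, 0] == 0  # G G
        assert g.calls[1, 1] == MISSING  # "0 0"
        assert (g.variants[0].a1, g.variants[0].a2) == ("A", "G")

    def test_het_first_call_takes_lexicographic_a1(self, tmp_path):
        ped, map_ = _write_toy_text(
            tmp_path, ["F 1 0 0 1 -9 G A"], ["1 snp1 0 500"]
        )
        g = read_plink_text(ped, map_)
        assert g.variants[0].a1 == "A"

    def test_round_trip_through_writer(self, tmp_path):
        ped, map_ = _write_toy_text(
            tmp_path,
            [
                "F a 0 0 1 -9 A A C T",
                "F b 0 0 2 -9 A G 0 0",
                "F c 0 0 0 -9 G G T T",
            ],
            ["1 p1 0 100", "2 p2 0 200"],
        )
        g = read_plink_text(ped, map_)
        write_plink_text(g, tmp_path / "o.ped", tmp_path / "o.map")
        g2 = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map")
        assert g2 == g
        # second pass is byte-stable
        write_plink_text(g2, tmp_path / "o2.ped", tmp_path / "o2.map")
        assert (tmp_path / "o2.ped").read_bytes() == (tmp_path / "o.ped").read_bytes()
        assert (tmp_path / "o2.map").read_bytes() == (tmp_path / "o.map").read_bytes()

    def test_ragged_ped_row_errors_with_line(self, tmp_path):
        ped, map_ = _write_toy_text(
            tmp_path, ["F 1 0 0 1 -9 A A"], ["1 s1 0 10", "1 s2 0 20"]
        )
        with pytest.raises(PlinkFormatError, match=":1"):
            read_plink_text(ped, map_)

    def test_triallelic_site_errors_with_variant(self, tmp_path):
        ped, map_ = _write_toy_text(
            tmp_path,
            ["F 1 0 0 1 -9 A A", "F 2 0 0 1 -9 C C", "F 3 0 0 1 -9 G G"],
            ["1 bad1 0 10"],
        )
        with pytest.raises(TriallelicError, match="bad1"):
            read_plink_text(ped, map_)


class TestPlinkBinary:
    def test_single_byte_hom_a2(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0xFF]))
        (tmp_path / "x.bim").write_text("1\tsnp1\t0\t100\tA\tG\n")
        (tmp_path / "x.fam").write_text("F 1 0 0 1 -9\n")
        g = read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam")
        assert g.calls[0, 0] == 0  # hom for a2

    def test_bytes_per_snp(self, tmp_path):
        g = make_matrix(np.zeros((5, 3), dtype=np.int8))
        write_plink_binary(g, tmp_path / "y.bed", tmp_path / "y.bim", tmp_path / "y.fam")
        data = (tmp_path / "y.bed").read_bytes()
        assert len(data) == 3 + 2 * 3  # magic+mode, ceil(5/4)=2 bytes per SNP

    def test_bad_magic(self, tmp_path):
        (tmp_path / "z.bed").write_bytes(b"\x00\x00\x01\x00")
        (tmp_path / "z.bim").write_text("1\ts\t0\t1\tA\tG\n")
        (tmp_path / "z.fam").write_text("F 1 0 0 1 -9\n")
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink_binary(tmp_path / "z.bed", tmp_path / "z.bim", tmp_path / "z.fam")

    def test_truncated_body(self, tmp_path):
        (tmp_path / "w.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]))
        (tmp_path / "w.bim").write_text("1\ts\t0\t1\tA\tG\n")
        (tmp_path / "w.fam").write_text("F 1 0 0 1 -9\n")
        with pytest.raises(PlinkFormatError, match="bytes"):
            read_plink_binary(tmp_path / "w.bed", tmp_path / "w.bim", tmp_path / "w.fam")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 9),
        m=st.integers(1, 25),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_identity(self, tmp_path_factory, n, m, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, 2, MISSING], size=(n, m)).astype(np.int8)
        g = make_matrix(calls)
        tmp = tmp_path_factory.mktemp("bin")
        write_plink_binary(g, tmp / "r.bed", tmp / "r.bim", tmp / "r.fam")
        g2 = read_plink_binary(tmp / "r.bed", tmp / "r.bim", tmp / "r.fam")
        assert g2 == g


class TestIntersectPanels:
    def test_set_intersection(self):
        g1 = make_matrix(np.zeros((2, 3), dtype=np.int8), start_bp=100)
        g2 = make_matrix(np.ones((2, 3), dtype=np.int8), start_bp=100_100)
        # positions g1: 100, 100100, 200100 ; g2: 100100, 200100, 300100
        o1, o2 = intersect_panels(g1, g2)
        assert [v.pos_bp for v in o1.variants] == [100_100, 200_100]
        assert [v.pos_bp for v in o1.variants] == [v.pos_bp for v in o2.variants]

    def test_flipped_alleles_swap_counts(self):
        g1 = make_matrix([[2, 0]], a1="A", a2="G")
        g2 = make_matrix([[2, MISSING]], a1="G", a2="A")
        o1, o2 = intersect_panels(g1, g2)
        assert o2.calls[0, 0] == 0  # 2 -> 0 after flip
        assert o2.calls[0, 1] == MISSING
        assert o2.variants[0].a1 == "A"

    def test_strand_ambiguous_mismatch_dropped(self):
        g1 = make_matrix([[1, 1]], a1="A", a2="T")
        g2_keep = make_matrix([[1, 1]], a1="A", a2="T")
        o1, _ = intersect_panels(g1, g2_keep)
        assert o1.n_variants == 2
        g2_flip = make_matrix([[1, 1]], a1="T", a2="A")
        with pytest.raises(ValueError, match="no usable"):
            intersect_panels(g1, g2_flip)

    def test_counts_match_brute_force_on_random_panels(self):
        rng = np.random.default_rng(7)
        pos1 = rng.choice(np.arange(1, 1000) * 100, size=50, replace=False)
        pos2 = rng.choice(np.arange(1, 1000) * 100, size=60, replace=False)
        shared = set(pos1) & set(pos2)
        v1 = [Variant(f"a{p}", "1", int(p), "A", "G") for p in sorted(pos1)]
        v2 = [Variant(f"b{p}", "1", int(p), "A", "G") for p in sorted(pos2)]
        g1 = GenotypeMatrix([SampleRecord("x")], v1, np.ones((1, 50), dtype=np.int8))
        g2 = GenotypeMatrix([SampleRecord("y")], v2, np.ones((1, 60), dtype=np.int8))
        o1, o2 = intersect_panels(g1, g2)
        assert o1.n_variants == o2.n_variants == len(shared)


class TestPedigreeValidation:
    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            PedigreeTable(
                [
                    SampleRecord("a", sire="c"),
                    SampleRecord("b", sire="a"),
                    SampleRecord("c", sire="b"),
                ]
            )

    def test_self_parent_rejected(self):
        with pytest.raises(PedigreeError):
            SampleRecord("a", sire="a")

    def test_autosome_flagging(self):
        v = Variant("x", "X", 100, "A", "G")
        assert not v.is_autosomal
        assert Variant("y", "18", 100, "A", "G").is_autosomal
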