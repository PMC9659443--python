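"""PLINK-format genotype and pedigree I/O.

Genotypes are held as counts of each variant's ``a1`` allele in
``{0, 1, 2, MISSING}``; ``MISSING`` is a distinct sentinel (-1) and is
never conflated with the homozygous-``a2`` call 0.  Positions are 1-based
throughout, matching PLINK conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call (stored in int8 call matrices).
MISSING: int = -1

#: Conventional label for an unknown parent in pedigree files.
UNKNOWN: str = "0"

_SEX_TO_PLINK = {"male": "1", "female": "2", "unknown": "0"}
_PLINK_TO_SEX = {"1": "male", "2": "female"}

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class PlinkFormatError(ValueError):
    """Raised when a PLINK file violates its format contract."""


class TriallelicError(PlinkFormatError):
    """Raised when more than two distinct alleles are observed at a site."""


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (cycles, self-parenting)."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP: name, chromosome, 1-based position and alleles."""

    id: str
    chrom: str
    pos_bp: int
    a1: str = "0"
    a2: str = "0"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"variant {self.id}: pos_bp must be >= 1")

    @property
    def is_autosomal(self) -> bool:
        """True for numeric chromosome labels (sex chroms are X/Y/XY/MT)."""
        return self.chrom.isdigit()

    @property
    def strand_ambiguous(self) -> bool:
        return frozenset((self.a1, self.a2)) in _AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class SampleRecord:
    id: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    sex: str = "unknown"
    generation: int | None = None

    def __post_init__(self) -> None:
        if self.id in (self.sire, self.dam):
            raise PedigreeError(f"individual {self.id} is its own parent")


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of a1-allele counts.

    ``calls`` is an int8 array with entries in {0, 1, 2, MISSING}.
    """

    samples: list[SampleRecord]
    variants: list[Variant]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = len(self.samples), len(self.variants)
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n} samples, {m} variants)"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain symbols outside {0,1,2,MISSING}")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != n:
            raise ValueError("duplicate sample ids")
        keys = [(v.chrom, v.pos_bp) for v in self.variants]
        if len(set(keys)) != m:
            raise ValueError("duplicate (chrom, pos_bp) variant keys")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def positions(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.variant_ids,
                "chrom": self.chromosomes(),
                "pos_bp": self.positions(),
                "a1": [v.a1 for v in self.variants],
                "a2": [v.a2 for v in self.variants],
            }
        )

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
            calls=self.calls[np.ix_(si, vi)].copy(),
        )

    def autosomal(self) -> "GenotypeMatrix":
        """Restrict to autosomes (sex chromosomes are read but flagged)."""
        keep = [j for j, v in enumerate(self.variants) if v.is_autosomal]
        return self.subset(variant_idx=keep)

    def sort_by_position(self) -> "GenotypeMatrix":
        order = sorted(
            range(self.n_variants),
            key=lambda j: (_chrom_sort_key(self.variants[j].chrom), self.variants[j].pos_bp),
        )
        return self.subset(variant_idx=order)

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant frequency of a1 over non-missing calls (NaN if none)."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class PedigreeTable:
    """Individual/sire/dam records forming a DAG; founders have UNKNOWN parents."""

    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}")

    def graph(self) -> nx.DiGraph:
        """Parent -> offspring digraph over known individuals."""
        g = nx.DiGraph()
        g.add_nodes_from(r.id for r in self.records)
        for r in self.records:
            for parent in (r.sire, r.dam):
                if parent != UNKNOWN:
                    g.add_edge(parent, r.id)
        return g

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes its offspring."""
        order = list(nx.lexicographical_topological_sort(self.graph()))
        known = set(self.ids)
        return [i for i in order if i in known]

    def parents(self, ind: str) -> tuple[str, str]:
        rec = next(r for r in self.records if r.id == ind)
        return rec.sire, rec.dam

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire for r in self.records],
                "dam": [r.dam for r in self.records],
                "sex": [r.sex for r in self.records],
                "generation": [r.generation for r in self.records],
            }
        )


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a 5-column pedigree: id sire dam sex generation ('0' = unknown)."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PedigreeError(f"{path}:{lineno}: expected >=4 columns, got {len(parts)}")
        gen = int(parts[4]) if len(parts) > 4 and parts[4] not in ("NA", ".") else None
        records.append(
            SampleRecord(
                id=parts[0],
                sire=parts[1],
                dam=parts[2],
                sex=parts[3] if parts[3] in ("male", "female") else _PLINK_TO_SEX.get(parts[3], "unknown"),
                generation=gen,
            )
        )
    return PedigreeTable(records)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    lines = [
        "\t".join(
            (
                r.id,
                r.sire,
                r.dam,
                r.sex,
                "NA" if r.generation is None else str(r.generation),
            )
        )
        for r in ped.records
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PED/MAP pair.

    Alleles are recoded to counts of ``a1``, where ``a1`` is the first allele
    observed at the site scanning samples in order (for a heterozygous first
    call the lexicographically smaller allele); "0 0" becomes MISSING.
    """
    variants_raw = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PlinkFormatError(f"{map_path}:{lineno}: MAP rows need 4 fields")
        variants_raw.append((parts[1], parts[0], int(parts[3])))
    m = len(variants_raw)

    samples: list[SampleRecord] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise PlinkFormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        samples.append(
            SampleRecord(
                id=parts[1],
                sire=parts[2],
                dam=parts[3],
                sex=_PLINK_TO_SEX.get(parts[4], "unknown"),
            )
        )
        allele_rows.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        )

    n = len(samples)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    variants: list[Variant] = []
    for j, (vid, chrom, pos) in enumerate(variants_raw):
        a1, a2 = _site_alleles([row[j] for row in allele_rows], vid)
        for i in range(n):
            x, y = allele_rows[i][j]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == a1) + (y == a1)
        variants.append(Variant(id=vid, chrom=chrom, pos_bp=pos, a1=a1, a2=a2))
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def _site_alleles(pairs: list[tuple[str, str]], vid: str) -> tuple[str, str]:
    a1 = a2 = "0"
    for x, y in pairs:
        if x == "0" or y == "0":
            continue
        if a1 == "0":
            a1 = min(x, y) if x != y else x
        for allele in (x, y):
            if allele == a1:
                continue
            if a2 == "0":
                a2 = allele
            elif allele != a2:
                raise TriallelicError(
                    f"variant {vid}: >2 alleles observed ({a1},{a2},{allele})"
                )
    return a1, a2


def write_plink_text(
    g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    map_lines = [
        f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}" for v in g.variants
    ]
    Path(map_path).write_text("\n".join(map_lines) + "\n")

    ped_lines = []
    for i, s in enumerate(g.samples):
        fields = ["FAM", s.id, s.sire, s.dam, _SEX_TO_PLINK[s.sex], "-9"]
        for j, v in enumerate(g.variants):
            c = g.calls[i, j]
            if c == MISSING:
                fields += ["0", "0"]
            elif c == 2:
                fields += [v.a1, v.a1]
            elif c == 1:
                fields += [v.a1, v.a2]
            else:
                fields += [v.a2, v.a2]
        ped_lines.append(" ".join(fields))
    Path(ped_path).write_text("\n".join(ped_lines) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM, v1 SNP-major)
# ---------------------------------------------------------------------------

_MAGIC = bytes((0x6C, 0x1B))
# 2-bit code -> count of BIM allele 1: 00 hom-a1, 01 missing, 10 het, 11 hom-a2
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def read_plink_binary(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypeMatrix:
    """Decode a PLINK v1 BED/BIM/FAM trio (SNP-major only)."""
    variants = []
    for lineno, line in enumerate(Path(bim_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        p = line.split()
        if len(p) < 6:
            raise PlinkFormatError(f"{bim_path}:{lineno}: BIM rows need 6 fields")
        variants.append(Variant(id=p[1], chrom=p[0], pos_bp=int(p[3]), a1=p[4], a2=p[5]))

    samples = []
    for line in Path(fam_path).read_text().splitlines():
        if not line.strip():
            continue
        p = line.split()
        samples.append(
            SampleRecord(id=p[1], sire=p[2], dam=p[3], sex=_PLINK_TO_SEX.get(p[4], "unknown"))
        )

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != b"\x01":
        raise PlinkFormatError(f"{bed_path}: only SNP-major mode (0x01) supported")
    n, m = len(samples), len(variants)
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes, found {body.size}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample index runs LSB-first within each byte
    codes = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _CODE_TO_CALL[codes].T.copy()
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_plink_binary(
    g: GenotypeMatrix, bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> None:
    bim_lines = [
        f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\t{v.a1}\t{v.a2}" for v in g.variants
    ]
    Path(bim_path).write_text("\n".join(bim_lines) + "\n")
    fam_lines = [
        f"FAM {s.id} {s.sire} {s.dam} {_SEX_TO_PLINK[s.sex]} -9" for s in g.samples
    ]
    Path(fam_path).write_text("\n".join(fam_lines) + "\n")

    n, m = g.n_samples, g.n_variants
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    call_codes = np.empty((m, n), dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        call_codes[g.calls.T == call] = code
    codes[:, :n] = call_codes  # trailing pad bits stay zero
    packed = (
        codes.reshape(m, bytes_per_snp, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=-1, dtype=np.uint8)
    Path(bed_path).write_bytes(_MAGIC + b"\x01" + packed.tobytes())


# ---------------------------------------------------------------------------
# Panel intersection
# ---------------------------------------------------------------------------


def intersect_panels(
    g1: GenotypeMatrix, g2: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two panels to their shared (chrom, pos_bp) sites.

    Allele orientation is harmonized by swapping counts where the panels'
    a1/a2 labels are flipped.  Sites whose allele labels disagree, and
    strand-ambiguous (A/T, C/G) sites that are not labelled identically in
    both panels, are dropped with a logged count.
    """
    idx2 = {(v.chrom, v.pos_bp): j for j, v in enumerate(g2.variants)}
    keep1: list[int] = []
    keep2: list[int] = []
    flip2: list[bool] = []
    n_dropped = 0
    for j1, v1 in enumerate(g1.variants):
        j2 = idx2.get((v1.chrom, v1.pos_bp))
        if j2 is None:
            continue
        v2 = g2.variants[j2]
        same = (v1.a1, v1.a2) == (v2.a1, v2.a2)
        flipped = (v1.a1, v1.a2) == (v2.a2, v2.a1)
        if v1.strand_ambiguous or v2.strand_ambiguous:
            if not same:
                n_dropped += 1
                continue
            flipped = False
        elif not (same or flipped):
            n_dropped += 1
            continue
        keep1.append(j1)
        keep2.append(j2)
        flip2.append(flipped and not same)
    if n_dropped:
        logger.info("intersect_panels: dropped %d allele-incompatible sites", n_dropped)
    if not keep1:
        raise ValueError("panels share no usable (chrom, pos_bp) sites")

    out1 = g1.subset(variant_idx=keep1)
    out2 = g2.subset(variant_idx=keep2)
    for k, do_flip in enumerate(flip2):
        if do_flip:
            col = out2.calls[:, k]
            swapped = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
            out2.calls[:, k] = swapped
            v = out2.variants[k]
            out2.variants[k] = replace(v, a1=v.a2, a2=v.a1)
    return out1, out2
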