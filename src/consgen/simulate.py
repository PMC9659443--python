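"""Synthetic-data generators for every pipeline stage.

Everything here is seed-deterministic and returns provenance metadata so
fixtures can be regenerated exactly: multi-generation pedigrees with known
inbreeding loops, gene-dropped genotypes (Mendelian transmission per
locus), two-or-more-ancestry admixed genotypes with known Q (Balding-
Nichols divergence), implanted homozygous tracts for ROH detection, and a
small recombining Wright-Fisher population for LD decay.

Loci are unlinked by default; linkage is simulated only where LD itself is
the object of study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plinkio import (
    MISSING,
    UNKNOWN,
    GenotypeMatrix,
    PedigreeTable,
    SampleRecord,
    Variant,
)

DEFAULT_FOUNDER_MAF = (0.05, 0.5)


@dataclass
class SimulationInfo:
    """Provenance: which generator, with which parameters and seed."""

    generator: str
    params: dict
    seed: int


def _default_variants(
    m: int, chrom: str = "1", spacing_bp: int = 100_000, start_bp: int = 1
) -> list[Variant]:
    return [
        Variant(id=f"snp{j + 1}", chrom=chrom, pos_bp=start_bp + j * spacing_bp, a1="A", a2="B")
        for j in range(m)
    ]


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mating_scheme: str = "random",
    seed: int = 0,
    offspring_per_generation: int | None = None,
    n_sires: int = 9,
    sows_per_sire: int = 3,
    offspring_per_sow: int = 2,
) -> tuple[PedigreeTable, SimulationInfo]:
    """Reproducible multi-generation pedigree.

    Schemes: ``random`` (random sire/dam pairs each generation),
    ``full-sib-loop`` (a founder pair, their full-sib offspring mated so
    generation >= 2 has F = 0.25), and ``sire-family`` (``n_sires`` sires
    each mated to distinct sows: paternal half-sib families).
    """
    rng = np.random.default_rng(seed)
    info = SimulationInfo(
        "simulate_pedigree",
        dict(
            n_founders=n_founders,
            n_generations=n_generations,
            mating_scheme=mating_scheme,
        ),
        seed,
    )
    if mating_scheme in ("random", "full-sib-loop") and n_founders < 2:
        raise ValueError("need at least 2 founders")

    records: list[SampleRecord] = []
    if mating_scheme == "random":
        males = [f"g0_m{i}" for i in range(max(1, n_founders // 2))]
        females = [f"g0_f{i}" for i in range(n_founders - len(males))]
        if not females:
            raise ValueError("random scheme needs founders of both sexes")
        for m_ in males:
            records.append(SampleRecord(m_, sex="male", generation=0))
        for f_ in females:
            records.append(SampleRecord(f_, sex="female", generation=0))
        n_off = offspring_per_generation or n_founders
        for gen in range(1, n_generations + 1):
            new_m, new_f = [], []
            for k in range(n_off):
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
                sex = "male" if k % 2 == 0 else "female"  # both sexes guaranteed
                ind = f"g{gen}_{'m' if sex == 'male' else 'f'}{k}"
                records.append(
                    SampleRecord(ind, sire=sire, dam=dam, sex=sex, generation=gen)
                )
                (new_m if sex == "male" else new_f).append(ind)
            males = new_m or males
            females = new_f or females
    elif mating_scheme == "full-sib-loop":
        records.append(SampleRecord("F0_s", sex="male", generation=0))
        records.append(SampleRecord("F0_d", sex="female", generation=0))
        prev = ("F0_s", "F0_d")
        for gen in range(1, n_generations + 1):
            bro = f"g{gen}_bro"
            sis = f"g{gen}_sis"
            records.append(SampleRecord(bro, sire=prev[0], dam=prev[1], sex="male", generation=gen))
            records.append(SampleRecord(sis, sire=prev[0], dam=prev[1], sex="female", generation=gen))
            prev = (bro, sis)
    elif mating_scheme == "sire-family":
        if n_generations < 1:
            raise ValueError("sire-family scheme needs >= 1 generation")
        for s in range(n_sires):
            records.append(SampleRecord(f"sire{s}", sex="male", generation=0))
            for w in range(sows_per_sire):
                sow = f"sow{s}_{w}"
                records.append(SampleRecord(sow, sex="female", generation=0))
                for o in range(offspring_per_sow):
                    sex = "male" if o == 0 else "female"
                    records.append(
                        SampleRecord(
                            f"fam{s}_off{w}_{o}",
                            sire=f"sire{s}",
                            dam=sow,
                            sex=sex,
                            generation=1,
                        )
                    )
    else:
        raise ValueError(f"unknown mating scheme {mating_scheme!r}")
    return PedigreeTable(records), info


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


def gene_drop(
    ped: PedigreeTable,
    m_snps: int,
    founder_maf_range: tuple[float, float] = DEFAULT_FOUNDER_MAF,
    seed: int = 0,
    missing_rate: float = 0.0,
    linked: bool = False,
    spacing_bp: int = 100_000,
    cm_per_mb: float = 1.0,
) -> tuple[GenotypeMatrix, SimulationInfo]:
    """Drop biallelic loci down a pedigree.

    Founder haplotype alleles are Bernoulli draws at per-locus frequencies
    from Uniform(*founder_maf_range*).  By default loci are unlinked (each
    offspring inherits one random parental allele per locus).  With
    ``linked=True`` each gamete is formed by Poisson-crossover
    recombination on a single-chromosome map (``cm_per_mb`` at the given
    physical spacing), so identity-by-descent forms contiguous tracts —
    required when ROH is the object of study.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*founder_maf_range, size=m_snps)
    variants = _default_variants(m_snps, spacing_bp=spacing_bp)
    cm_pos = np.array([v.pos_bp for v in variants]) / 1e6 * cm_per_mb
    L_morgan = (cm_pos[-1] - cm_pos[0]) / 100.0
    order = ped.topological_order()
    rec = {r.id: r for r in ped.records}
    hap: dict[str, np.ndarray] = {}
    for ind in order:
        r = rec[ind]
        h = np.empty((2, m_snps), dtype=np.int8)
        for hi, parent in enumerate((r.sire, r.dam)):
            if parent == UNKNOWN or parent not in hap:
                h[hi] = rng.random(m_snps) < freqs
            elif linked:
                h[hi] = _gamete(hap[parent][0], hap[parent][1], cm_pos, L_morgan, rng)
            else:
                pick = rng.integers(2, size=m_snps)
                h[hi] = hap[parent][pick, np.arange(m_snps)]
        hap[ind] = h
    ids = ped.ids
    calls = np.stack([hap[i].sum(axis=0) for i in ids]).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    samples = [rec[i] for i in ids]
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    info = SimulationInfo(
        "gene_drop",
        dict(m_snps=m_snps, founder_maf_range=founder_maf_range,
             missing_rate=missing_rate, linked=linked, spacing_bp=spacing_bp),
        seed,
    )
    return g, info


def mendelian_consistent(g: GenotypeMatrix, ped: PedigreeTable) -> bool:
    """Post-hoc validator: every child call is compatible with its parents.

    A child cannot carry more copies of an allele than its parents can
    jointly transmit (each parent transmits exactly one allele).
    """
    index = {s: i for i, s in enumerate(g.sample_ids)}
    rec = {r.id: r for r in ped.records}
    for ind, i in index.items():
        r = rec.get(ind)
        if r is None:
            continue
        for parent_id in (r.sire, r.dam):
            if parent_id == UNKNOWN or parent_id not in index:
                continue
            p = g.calls[index[parent_id]]
            c = g.calls[i]
            ok = (c == MISSING) | (p == MISSING) | ~(((p == 2) & (c == 0)) | ((p == 0) & (c == 2)))
            if not ok.all():
                return False
    return True


# ---------------------------------------------------------------------------
# Admixture (Balding-Nichols)
# ---------------------------------------------------------------------------


def simulate_admixed(
    n: int,
    m: int,
    K: int = 2,
    fst: float | tuple[float, ...] = 0.2,
    q_dirichlet_alpha: float | tuple[float, ...] = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray, SimulationInfo]:
    """Admixed genotypes with known ground-truth Q and F.

    Ancestral frequencies follow the Balding-Nichols model: for each SNP
    with shared ancestral frequency p0 ~ U(0.1, 0.9), population k draws
    f_kj ~ Beta(p0 (1-Fst_k)/Fst_k, (1-p0)(1-Fst_k)/Fst_k).  Individual
    ancestry rows come from a Dirichlet; genotypes are Binomial(2, qF).
    """
    rng = np.random.default_rng(seed)
    fst_arr = np.broadcast_to(np.asarray(fst, dtype=float), (K,))
    if ((fst_arr <= 0) | (fst_arr >= 1)).any():
        raise ValueError("fst must lie in (0, 1)")
    alpha = np.broadcast_to(np.asarray(q_dirichlet_alpha, dtype=float), (K,))
    p0 = rng.uniform(0.1, 0.9, size=m)
    F = np.empty((K, m))
    for k in range(K):
        lam = (1.0 - fst_arr[k]) / fst_arr[k]
        F[k] = rng.beta(p0 * lam, (1.0 - p0) * lam)
    F = np.clip(F, 1e-4, 1 - 1e-4)
    Q = rng.dirichlet(alpha, size=n)
    P = Q @ F
    calls = rng.binomial(2, P).astype(np.int8)
    samples = [SampleRecord(id=f"ind{i + 1}") for i in range(n)]
    g = GenotypeMatrix(samples=samples, variants=_default_variants(m), calls=calls)
    info = SimulationInfo(
        "simulate_admixed",
        dict(n=n, m=m, K=K, fst=fst_arr.tolist(), alpha=alpha.tolist()),
        seed,
    )
    return g, Q, F, info


def simulate_inbred(
    n: int, m: int, f: float, seed: int = 0
) -> tuple[GenotypeMatrix, SimulationInfo]:
    """Genotypes with a planted individual inbreeding coefficient.

    At each locus an individual is autozygous with probability ``f``
    (genotype 2*Bernoulli(p)) and in Hardy-Weinberg proportions otherwise.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*DEFAULT_FOUNDER_MAF, size=m)
    ibd = rng.random((n, m)) < f
    hwe = rng.binomial(2, np.broadcast_to(p, (n, m)))
    auto = 2 * rng.binomial(1, np.broadcast_to(p, (n, m)))
    calls = np.where(ibd, auto, hwe).astype(np.int8)
    samples = [SampleRecord(id=f"ind{i + 1}") for i in range(n)]
    g = GenotypeMatrix(samples=samples, variants=_default_variants(m), calls=calls)
    return g, SimulationInfo("simulate_inbred", dict(n=n, m=m, f=f), seed)


# ---------------------------------------------------------------------------
# ROH implanting
# ---------------------------------------------------------------------------


def implant_roh(
    g: GenotypeMatrix,
    sample_id: str,
    chrom: str,
    start_bp: int,
    length_mb: float,
) -> tuple[GenotypeMatrix, tuple[int, int]]:
    """Set the spanned SNPs homozygous for their major allele.

    Returns a modified copy and the implanted (start_bp, end_bp) interval
    for oracle comparison; missing calls inside the tract become
    homozygous too.  A zero-length request is a no-op.
    """
    if length_mb <= 0:
        return g.subset(), (start_bp, start_bp - 1)
    end_bp = start_bp + int(length_mb * 1e6) - 1
    out = g.subset()
    i = out.sample_ids.index(sample_id)
    p = out.allele_frequencies()
    for j, v in enumerate(out.variants):
        if v.chrom == chrom and start_bp <= v.pos_bp <= end_bp:
            out.calls[i, j] = 2 if (np.isfinite(p[j]) and p[j] >= 0.5) else 0
    return out, (start_bp, end_bp)


# ---------------------------------------------------------------------------
# Wright-Fisher with recombination
# ---------------------------------------------------------------------------


def simulate_wf(
    n_e: int,
    n_generations: int,
    m_snps: int,
    chrom_length_cm: float = 100.0,
    seed: int = 0,
    n_sample: int | None = None,
) -> tuple[GenotypeMatrix, SimulationInfo]:
    """Discrete-generation diploid Wright-Fisher population with
    recombination; returns a final-generation sample.

    ``m_snps`` loci sit evenly on a ``chrom_length_cm`` map; physical
    positions use 1 cM = 1 Mb.  Each offspring draws two random parents;
    each gamete recombines with Poisson(map length in Morgans) crossovers
    at uniform map positions.  Initial haplotype frequencies ~ U(0.1, 0.9).
    """
    rng = np.random.default_rng(seed)
    cm_pos = np.linspace(0.0, chrom_length_cm, m_snps)
    p0 = rng.uniform(0.1, 0.9, size=m_snps)
    haps = (rng.random((2 * n_e, m_snps)) < p0).astype(np.int8)
    L_morgan = chrom_length_cm / 100.0

    for _ in range(n_generations):
        new = np.empty_like(haps)
        parents = rng.integers(n_e, size=(n_e, 2))
        for i in range(n_e):
            for gi in range(2):
                par = parents[i, gi]
                new[2 * i + gi] = _gamete(haps[2 * par], haps[2 * par + 1], cm_pos, L_morgan, rng)
        haps = new

    n_sample = n_e if n_sample is None else min(n_sample, n_e)
    pick = rng.choice(n_e, size=n_sample, replace=False)
    calls = (haps[2 * pick] + haps[2 * pick + 1]).astype(np.int8)
    bp = (cm_pos * 1e6).astype(np.int64) + 1
    variants = [
        Variant(id=f"wf{j + 1}", chrom="1", pos_bp=int(bp[j]), a1="A", a2="B")
        for j in range(m_snps)
    ]
    samples = [SampleRecord(id=f"wf_ind{i + 1}") for i in range(n_sample)]
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    info = SimulationInfo(
        "simulate_wf",
        dict(n_e=n_e, n_generations=n_generations, m_snps=m_snps, chrom_length_cm=chrom_length_cm),
        seed,
    )
    return g, info


def _gamete(h1, h2, cm_pos, L_morgan, rng) -> np.ndarray:
    k = rng.poisson(L_morgan)
    phase = rng.integers(2)
    if k == 0:
        return (h1 if phase == 0 else h2).copy()
    cuts = np.sort(rng.uniform(0.0, cm_pos[-1], size=k))
    seg = np.searchsorted(cuts, cm_pos, side="right")
    use_h1 = (seg + phase) % 2 == 0
    return np.where(use_h1, h1, h2)
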