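import numpy as np
import pytest

from consgen.plinkio import (
    MISSING,
    GenotypeMatrix,
    PedigreeTable,
    SampleRecord,
    Variant,
)


def make_matrix(calls, chrom="1", spacing_bp=100_000, start_bp=1, a1="A", a2="B"):
    """GenotypeMatrix from a nested list / array of calls (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = [SampleRecord(id=f"s{i + 1}") for i in range(n)]
    variants = [
        Variant(id=f"v{j + 1}", chrom=chrom, pos_bp=start_bp + j * spacing_bp, a1=a1, a2=a2)
        for j in range(m)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


@pytest.fixture
def toy_matrix():
    return make_matrix([[2, 1, 0], [1, 1, MISSING], [0, 2, 2]])


@pytest.fixture
def fullsib_pedigree():
    """Two founders, their full-sib offspring, and an inbred grandchild."""
    return PedigreeTable(
        [
            SampleRecord("sire0", sex="male"),
            SampleRecord("dam0", sex="female"),
            SampleRecord("sonA", sire="sire0", dam="dam0", sex="male"),
            SampleRecord("dauB", sire="sire0", dam="dam0", sex="female"),
            SampleRecord("inbredX", sire="sonA", dam="dauB", sex="male"),
        ]
    )


@pytest.fixture
def cousin_pedigree():
    """First-cousin mating: offspring has F = 0.0625."""
    recs = [
        SampleRecord("gs", sex="male"),
        SampleRecord("gd", sex="female"),
        SampleRecord("p1", sire="gs", dam="gd", sex="male"),
        SampleRecord("p2", sire="gs", dam="gd", sex="female"),
        SampleRecord("u1", sex="female"),
        SampleRecord("u2", sex="male"),
        SampleRecord("c1", sire="p1", dam="u1", sex="male"),
        SampleRecord("c2", sire="u2", dam="p2", sex="female"),
        SampleRecord("off", sire="c1", dam="c2", sex="male"),
    ]
    return PedigreeTable(recs)


def random_pedigree(rng, n_founders=6, n_generations=5, per_gen=6):
    """Random multi-generation pedigree for oracle comparisons."""
    males = [f"m0_{i}" for i in range(n_founders // 2)]
    females = [f"f0_{i}" for i in range(n_founders - n_founders // 2)]
    recs = [SampleRecord(i, sex="male") for i in males]
    recs += [SampleRecord(i, sex="female") for i in females]
    for gen in range(1, n_generations + 1):
        new_m, new_f = [], []
        for k in range(per_gen):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            sex = "male" if k % 2 == 0 else "female"
            ind = f"{'m' if sex == 'male' else 'f'}{gen}_{k}"
            recs.append(SampleRecord(ind, sire=sire, dam=dam, sex=sex, generation=gen))
            (new_m if sex == "male" else new_f).append(ind)
        males, females = new_m, new_f
    return PedigreeTable(recs)


def kinship_oracle(ped: PedigreeTable):
    """Independent relationship oracle via the recursive kinship coefficient.

    phi(a, a) = (1 + F_a)/2 with F_a = phi(sire_a, dam_a);
    phi(a, b) = (phi(sire_a, b) + phi(dam_a, b))/2  for a younger than b.
    The numerator relationship is 2*phi.
    """
    order = {ind: k for k, ind in enumerate(ped.topological_order())}
    rec = {r.id: r for r in ped.records}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def phi(a, b):
        if a is None or b is None:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        ra = rec[a]
        sa = ra.sire if ra.sire in rec else None
        da = ra.dam if ra.dam in rec else None
        if a == b:
            return 0.5 * (1.0 + phi(sa, da))
        return 0.5 * (phi(sa, b) + phi(da, b))

    ids = ped.ids
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2.0 * phi(ids[i], ids[j])
    return ids, A


def brute_force_roh(pos, row, min_snp, min_length_kb, min_density_kb_per_snp):
    """Maximal fully-homozygous runs (no het, no missing) with the
    run-level count/length/density filters; independent of the detector."""
    segs = []
    start = None
    hom = (row == 0) | (row == 2)
    for j in range(len(pos) + 1):
        if j < len(pos) and hom[j]:
            if start is None:
                start = j
            continue
        if start is not None:
            e = j - 1
            n = e - start + 1
            length_kb = (pos[e] - pos[start] + 1) / 1e3
            if (
                n >= min_snp
                and length_kb >= min_length_kb
                and length_kb / n <= min_density_kb_per_snp
            ):
                segs.append((int(pos[start]), int(pos[e]), n))
            start = None
    return segs


def brute_force_complete_linkage(d, threshold_height):
    """Exhaustive agglomeration: repeatedly merge the two clusters with the
    smallest maximum pairwise distance, stopping above the cut height."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        if h > threshold_height:
            break
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(sorted(clusters, key=min)):
        for i in c:
            labels[i] = lab + 1
    return labels
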