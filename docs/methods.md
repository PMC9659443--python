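# Methods

This note records the statistical models implemented in `consgen`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that matter when
comparing output with other software.

## Genotype representation and I/O

Genotypes are counts of each variant's `a1` allele in {0, 1, 2}, with a
distinct `MISSING` sentinel (−1); "no call" is never conflated with a
homozygous call. Positions are 1-based and all exported intervals are
1-based inclusive (PLINK convention); the BED export converts to 0-based
half-open coordinates. The binary codec implements PLINK v1 SNP-major
files bit-exactly (00 = hom `a1`, 01 = missing, 10 = het, 11 = hom `a2`,
samples packed LSB-first, zero pad bits). In text (PED/MAP) input, where
allele labels are not declared, `a1` is the first allele observed
scanning samples in order, taking the lexicographically smaller allele
when the first call is heterozygous — a deterministic rule that makes
write→read a round trip.

When two chips are merged, sites are matched on (chromosome, position).
If the allele pair is flipped between panels the counts are swapped;
A/T and C/G sites are strand-ambiguous, so they are kept only when the
labels match exactly in both panels and dropped (with a logged count)
otherwise. No strand complementing is attempted: on arrays with mixed
strand conventions that guess is wrong often enough to be dangerous.
Sex chromosomes are read and flagged; only autosomes flow into analysis.

## QC and diversity

Filters run sequentially — autosomes, sample call rate (default ≥ 0.90),
SNP call rate (≥ 0.90), MAF (≥ 0.01), HWE exact p (≥ 10⁻⁶) — and each
step's removal count is measured on the survivors of the previous step,
so the report reproduces the bookkeeping style of array-QC pipelines
(`retained = autosomal − callrate − maf − hwe`).

The HWE test is the exact conditional test on the heterozygote count
given the allele counts: all het counts with probability not exceeding
the observed one are summed (two-sided, no mid-p). Probabilities come
from the standard two-step recurrence evaluated in log space, which is
stable out to thousands of samples; a brute-force enumeration oracle
verifies every table with n ≤ 50 in the test suite.

He is plain 2p̂(1−p̂) without the n/(n−1) small-sample correction,
matching PLINK's `E(HET)` column; Ho, He and MAF are SNP-averaged (the
per-individual average is the other defensible choice; SNP-averaging is
what array QC software reports). PN counts SNPs with MAF ≥ 0.01 — the
same threshold as the QC filter, so PN is also meaningful pre-QC.

## Runs of homozygosity

The detector follows the PLINK `--homozyg` design. A 50-SNP window
passes when it contains at most one heterozygous and at most one missing
call; a SNP is eligible when the fraction of passing windows overlapping
it (among windows that fit on the chromosome) reaches 0.05; maximal runs
of eligible SNPs become candidate segments. Run-level constraints are
then applied: splits at inter-SNP gaps > 1000 kb, the same ≤1-het/≤1-missing
allowance enforced over each whole segment (splitting greedily
left-to-right when exceeded), ends trimmed to homozygous called SNPs,
and finally the printed criteria — ≥ 30 SNPs, ≥ 1000 kb, density of at
least one SNP per 1000 kb. Every emitted segment therefore satisfies all
four criteria, and the test suite re-checks this post hoc, independently
of the detector.

A boundary note: with the strictest settings (no het/missing tolerance)
the window rule "at least one fully homozygous overlapping window"
makes the detector exactly equal to a maximal-homozygous-run scanner
for runs of at least one window length. Demanding that *all* overlapping
windows pass instead trims roughly a window's worth of SNPs from each
run end (edge windows straddle the run boundary), which is why the
oracle-equivalence tests use a tiny positive hit threshold.

Length classes are [1,5), [5,10) and ≥10 Mb; a 10.0 Mb segment is ">10 Mb"
by this convention, and sub-1 Mb segments are retained raw but
unclassified. Genome coverage uses L_AUTO = 2,450,462.292 kb (the porcine
autosomal map of the motivating 50K panel) as the default denominator.

## Inbreeding coefficients

* `f_ped` — A_ii − 1 from the numerator relationship matrix (below).
* `f_roh` — per length class, the summed segment length over L_AUTO.
  Long ROH (>10 Mb) reflect inbreeding within ~5 generations; 1–5 Mb
  segments reflect older coancestry.
* `f_snp` — the three marker-based estimators reported by GCTA `--ibc`,
  with in-sample allele frequencies: F̂₁ is the mean per-SNP
  (x−2p)²/2pq − 1, F̂₂ = 1 − Σhet/Σ2pq (excess homozygosity, PLINK
  `--het` style with ratio-of-sums weighting), F̂₃ the mean per-SNP
  [x² − (1+2p)x + 2p²]/2pq (correlation between uniting gametes). F̂₃ is
  the headline value; all three are stored. SNPs fixed in the sample are
  excluded.

Because frequencies are estimated from the analyzed sample itself, all
three estimators (and the G off-diagonal mean) carry a structural bias
of order −1/n; at n = 20 this is ≈ −0.03 and it is *not* an
implementation artifact. Property tests therefore assert near-zero means
at n = 200, where the bias is well inside the tolerance. Correlation
p-values use the t transform with no multiple-testing correction.

## LD and effective population size

r² is the squared Pearson correlation of unphased 0/1/2 genotype vectors
over pairwise-complete samples (composite LD — the right quantity for
unphased array data), computed within chromosomes and binned by physical
distance; default bin upper edges are 0.5, 1, 2, 5, 10 and 100 Mb. The
drift expectation Ne = (1/4c)(1/r² − 1) is applied to each bin's mean r²
at the bin midpoint converted at 1 cM per Mb. Generation depth defaults
to t = 1/(2c); the published six-bin mapping (200, 50, 20, 10, 5, 0
generations) is available as the preset `paper2022` because the two
conventions disagree (e.g. 0.5 Mb → 100 generations under t = 1/(2c))
and both should be reproducible. The finite-sample inflation of r²
(≈ 1/n) can optionally be subtracted; it is off by default since the
published equation carries no such term, which also means estimates at
large distances (r² near the noise floor) are biased downward unless the
sample is large.

## Relationship matrices and families

A is built by the tabular recursion (A_ii = 1 + ½A_sire,dam, A_ij =
½(A_j,sire + A_j,dam), unknown parents contribute 0) over a topological
order of the pedigree DAG; an independent recursive-kinship oracle
checks it on random pedigrees. G is VanRaden method 1, ZZ′/2Σp̂q̂ with
per-SNP mean imputation of missing calls. H is the standard single-step
combination with blending G_w = (1−w)G + wA₂₂ (default w = 0.05; w = 0
reproduces H ≡ G exactly when everyone is genotyped, and H ≡ A when no
one is — both limits are tested to machine precision).

"Kinship coefficient" here means the relationship-matrix entry itself
(parent–offspring 0.5), not half of it: the 0.0625 family threshold and
the distance D = 1 − r are applied directly to matrix entries. D is
clamped to 0 where r > 1 (possible on G diagonals and duplicates), with
a warning.

Families: boars are clustered by complete linkage on D and the tree is
cut at height 1 − 0.0625 = 0.9375, so two boars end up in the same
family precisely when their cluster's maximum distance stays below the
cut — i.e. no two boars related at ≥ 0.0625 can land in different
families. (Read literally, the source convention "kinship below 0.0625
→ same family" inverts the breeding rationale of keeping relatives
together; the standard reading is implemented.) A fixed family count is
also supported, since with pedigree-only matrices the same herd can
split into a different number of families than with genomic matrices.
Non-boars join the family with the smallest mean distance to its boars,
ties broken toward the smallest family index and logged. The dendrogram
is exported as an ultrametric Newick tree (leaves at height 0, internal
nodes at half their merge distance).

## Ancestry at fixed K

The model is the standard admixture likelihood: genotype x_ij ~
Binomial(2, Σ_k q_ik f_kj). It is maximized by plain EM (the classic
update equations) from multiple random starts — the quasi-Newton block
relaxation used by dedicated software reaches the same stationary
points; EM was chosen because its monotone-likelihood property is
asserted at every iteration, which makes the implementation
self-checking. Q rows are renormalized each step; F is clipped to
[10⁻⁶, 1−10⁻⁶]. Missing calls drop out of both updates. K is a user
input; cross-validated selection of K is deliberately out of scope.
Greedy windowed LD pruning (drop the later SNP of any within-window pair
with r² > 0.5) precedes fitting.

The target ("indigenous") lineage is identified as the Q column with the
highest mean over user-designated reference individuals. The
four-category split uses strict inequalities on the lower boundary of
each class: Min1 p > mean, Min2 mean−SD < p ≤ mean, Min3 mean−2SD < p ≤
mean−SD, Min4 p ≤ mean−2SD; the nucleus population is Min1 ∪ Min2,
which satisfies both phrasings of the published rule ("above mean minus
one SD").

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* each analysis needs
— Mendelian transmission down known pedigrees (with optional Poisson
crossover recombination at 1 cM/Mb when tract structure matters),
Balding–Nichols allele-frequency divergence at a chosen Fst with known
Q, implanted homozygous tracts, and a discrete-generation recombining
Wright–Fisher population for LD decay. They do not emulate array
ascertainment bias, genotyping-error patterns, real porcine
recombination-map heterogeneity, or selection. Passing tests therefore
demonstrate algorithmic correctness and parameter recovery under the
stated models, not robustness to array artifacts.

Defaults: founder MAF ~ U(0.05, 0.5); loci unlinked except where LD is
the object; Wright–Fisher runs use a single 100 cM chromosome. Problem
sizes in the test and acceptance runs (e.g. admixture at n = 60,
m = 5000; inbreeding recovery at n = 200, m = 5000; ten Wright–Fisher
replicates at N = 50) were chosen as the smallest sizes at which the
sampling noise of each check is clearly below its tolerance.

## Known limitations

* No VCF input, imputation or build liftover; PLINK dialects only.
* Allele mismatch between merged chips is resolved by drop-and-log only.
* Ne estimation inherits all caveats of the LD method: unphased
  composite r², no recombination-map correction, downward bias at large
  distances without the 1/n adjustment.
* The admixture fit is unsupervised; projection onto fixed reference
  panels is not implemented.
* H-matrix construction requires an invertible A₂₂ (duplicate pedigree
  entries must be resolved upstream).
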