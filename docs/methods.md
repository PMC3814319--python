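# Methods

This note documents the models, estimators and numerical choices behind
`kirco`, what the synthetic cohort generator does and does not emulate, and
the problem sizes the test suite and `scripts/acceptance.py` use.

## Cohort model and phasing

The unit of data is a mother-child cohort typed at two unlinked loci: a
KIR-like locus whose haplotypes vary in gene content (absence is the
reserved allele `ABSENT` and participates in every computation as an
allele), and a three-gene HLA-like class I locus. Genotypes are unphased
per-gene diploid allele pairs.

**Segregation phasing.** For each mother-child pair we enumerate every
split of the child's genotype into two gene-wise consistent haplotypes
(2^(h−1) unordered splits for h heterozygous genes) and keep the ordered
(maternal, paternal) assignments in which the maternal haplotype can be
drawn gene-by-gene from the mother's genotype. A unique surviving
assignment resolves the child — and the mother, whose second haplotype
follows by complement. No consistent assignment raises a Mendelian error
naming the offending gene. Ambiguous children are not guessed.

**EM phasing.** Unrelated individuals and segregation-ambiguous children
are phased by a standard multilocus haplotype-frequency EM in which the
segregation-deduced haplotype counts enter as Dirichlet pseudo-counts
(weight configurable, default 1 per observed count). Ambiguous children's
admissible pairs stay constrained to their segregation-consistent
candidates, so an EM assignment always implies a maternal orientation and
lets the mother be phased too. The penalized log-likelihood is monotone by
construction; maximum-posterior assignment breaks ties by the
lexicographically smallest pair, making the output deterministic. This is a
deliberate replacement for coalescent-informed Bayesian phasing: at the
heterozygosity levels this design targets (haplotype H ≥ 0.9), ambiguity is
rare and truth-recovery, not posterior calibration, is the acceptance
surface.

**Censuses.** The default "independently segregating" haplotype set counts
both haplotypes of every child and unrelated individual (2N = 262 for 104
pairs + 27 unrelated); a flag adds each mother's non-transmitted haplotype
(2N = 366). Allotype-level censuses collapse synonymous variants and map
expression-null alleles to a per-gene null class.

## Ligand-receptor pair counting

Epitopes are assigned from mature-protein sequence: Bw4 requires the
configured 77–83 motif with arginine 83; HLA-C carries C1 with asparagine
80 and C2 otherwise (with the B*46/B*73 C1 exceptions name-based); A3/11 is
name-based because the KIR3DL2-binding determinants of HLA-A are not
established. The interaction table is data (JSON), with additive gene-level
rules, allotype-level exception hooks (e.g. KIR2DL2's cross-reactive C2
ligands, including C*04:01), and expression-null lists (KIR3DL1*004 by
default). The per-individual statistic — the number of distinct viable
(KIR allotype, HLA allotype) pairs — is a set count: phase-independent and
invariant to homozygosity.

## Selection statistics

**Tajima's D** is computed from the gapped concatenated haplotype
alignment with the standard constants in n. Sites containing any gap (gene
absence) are excluded from the segregating-site count S; the mean pairwise
difference π uses pairwise deletion. These two deletion rules differ by
design: S is a site-level quantity and a gap makes the site's allele count
ill-defined, while π is a pair-level quantity for which pairwise deletion
retains information; the same convention is used for mismatch
distributions. S = 0 flags D as undefined rather than raising.

**Coalescent significance.** Empirical two-tail p-values come from a
built-in Hudson-style coalescent with infinite-sites mutation (rate θ/2 per
lineage per unit of 2N₀-scaled time) under piecewise-constant demographic
models. Bundled models (constant; ancient expansion = 10× growth at 0.5
time units; bottleneck-expansion; repeated-bottleneck) are config entries
with documented defaults; no result depends on their exact parameter
values, which the source literature does not print. p = 2·min(rank
tails)/(reps+1) with add-one correction, capped at 1; undefined-D
replicates are dropped with a logged count. The simulator is validated
against closed forms (E[π] = θ at n = 2, E[S] = θ·a₁) and cross-checked
against msprime with matched time scaling.

**Ewens–Watterson / Slatkin.** F = Σp² on any spectrum; the null
conditional on (k, n) is sampled by Chinese-restaurant construction
(vectorised across replicates) with θ solved from E[k] = k and rejection on
the realized k — conditional on k the Ewens configuration distribution is
θ-free, so the rejection is exact and θ only controls the acceptance rate.
p_Slatkin = Pr(F_sim ≤ F_obs) with add-one correction; F_nd = (F_obs −
mean F_sim)/SD F_sim, so negative values indicate spectra more even than
neutral (balancing selection). The default null size is 10,000 (tests use
1,000–2,000 where noted). Monomorphic spectra (k = 1) are flagged, not
tested.

**Motif projection** collapses allotypes by the identity of their residue
substring on a named binding-site set (peptide pockets, TCR, KIR, LILR,
CD8; residues appearing in exactly one named site form the "exclusive"
sets actually tested), summing frequencies; the operation is idempotent.

## Haplotype structure

Hamming distances on gapped concatenations count gap-vs-base as one
mutational step and gap-vs-gap as a match, so gene absence behaves as a
character state. Networks are minimum spanning trees (Kruskal with
deterministic label-order tie-break); a non-tree pair is an alternative
link when its distance equals the maximum tree-edge weight on the path
between the two nodes (an equally parsimonious displaced connection; the
zero-tolerance rule). Node probabilities use a statistical-parsimony
formulation implemented here as the uniform-placement multiple-hit
probability P(j, m) = Π_{i<j}(1 − i/m) — the probability that j
substitutions hit j distinct sites of m, i.e. that the observed differences
equal the true number of changes. It satisfies P(0) = 1, monotone
non-increase in j, and growth with m; the classical formulation carries
additional model parameters whose reference implementation is not
reproduced here.

Sliding-window MAF profiles average per-marker minor-allele frequencies
over fully contained windows (default 15 × 1); gene-presence enters the
marker series as a biallelic pseudo-marker per gene. Percentile ranking of
a window mean is its empirical rank in a user-supplied reference
distribution.

## Co-evolution scan

Each individual is represented, per gene and residue subset, by its two
phased residue strings concatenated in lexicographic order — this canonical
ordering makes every distance independent of the phase representation.
Distances are p-distances with pairwise deletion over gaps (absent genes).
The Mantel statistic is z = Σ_{i<j} A_ij·B_ij with a one-tailed upper
permutation p and add-one correction; the implementation also reports the
Pearson correlation r of the off-diagonal vectors, which equals z on
standardized matrices and is therefore scale-free.

The scan proceeds: (1) each polymorphic HLA residue against each
whole-gene KIR matrix; (2) stage-1 significant residues against single KIR
residues; (3) significant residues are expanded with any same-gene residue
in r² ≥ threshold LD with one of them (default threshold 1.0 = perfect LD)
and merged into LD groups by connected components — the expansion makes
groups robust to borderline single-residue permutation noise; (4)
group-vs-group tests, ranked by r with deterministic tie-breaks, re-tested
(capped at 10 rounds) until the ranking is stable. Stage gates use raw
alpha (0.05) to mirror the iterative procedure; Bonferroni-adjusted
p-values are reported alongside. Multiallelic LD uses allele-frequency-
weighted averages of per-allele-pair normalizations (r² = Σpᵢqⱼr²ᵢⱼ,
D′ = ΣpᵢqⱼD′ᵢⱼ). An empty significant set at any stage returns an empty
result, logged.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
haplotype pools over both loci, Hardy-Weinberg pairing, Mendelian
mother-child transmission with latent (unsampled) fathers, optional
crossover between the centromeric and telomeric KIR segments at the gene
boundary (configurable index; default rate 0), and independent segregation
of the two loci. Pool spectra are imposed, not evolved: `balanced`
(symmetric Dirichlet, concentration 100), `directional` (one class above
0.85 by construction), or `neutral_coalescent` (class frequencies of one
constant-size coalescent replicate conditioned on k). Default study shape:
104 pairs + 27 unrelated, 20-haplotype pools per locus.

Planted coupling biases joint sampling by rejection at the individual
level: an individual whose HLA residue-class dosage differs from its KIR
residue-class dosage is rejected with probability equal to the coupling
strength (strength 0 reproduces independence exactly, bit-for-bit). The
coupling demo configuration plants an HLA-B trio (24, 45, 97) against the
KIR3DL1 D0 pair (31, 44), each perfectly linked within its gene and
stratified to intermediate class frequency in the pool — a coupling planted
on a near-fixed class would be unidentifiable by construction. Synthetic
allele sequences are arbitrary backbones carrying the correct
epitope-determining residues (Bw4/Bw6 windows, HLA-C position 80), so the
default epitope rules and interaction table apply unchanged and truth pair
counts are computable.

What the generator does **not** emulate: copy-number variation beyond
diploid two-per-gene (a duplication-carrying haplotype is representable in
the data model but never simulated), intragenic recombination,
genotyping error, novel-allele discovery, and realistic allele sequences —
passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to real-data artefacts.

## Determinism and problem sizes

A single global seed fans out to per-stage substreams by stable hashing of
stage names; identical configurations give byte-identical outputs. The
test suite uses: 20,000 coalescent replicates for closed-form checks;
1,000 replicates (n = 50, θ = 5) for the neutral D calibration; exhaustive
Ewens enumeration for all n ≤ 8, k ≤ 4 against 3,000 accepted Monte-Carlo
configurations; 1,000 null spectra (n = 50) for the F_nd mean; 500
independent-matrix trials at 1,000 permutations for Mantel type-I error;
100 pairs + 27 unrelated for phasing truth-recovery; and 100 replicate
n = 200 cohorts (stage permutations 99, final groups 999) for scan
truth-recovery, with 25 null cohorts for the stage-1 discovery rate.
`scripts/acceptance.py` recomputes the same quantities at moderately
reduced replicate counts (stated in its JSON output as `n`).

## Known limitations

- The EM phaser ignores genotyping error and recombination within a
  transmission; haplotypes are treated as transmitted intact.
- The interaction table ships gene-level rules with a small exception list;
  peptide dependence and binding affinity are out of scope.
- The haplotype-motif nomenclature's third field (synonymous/non-coding
  differences) is parsed but never exercised on non-coding data.
- Mantel tests assume a single unstructured population; no correction for
  cryptic structure is applied.
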