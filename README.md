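# kirco — population immunogenetics of KIR and HLA class I

Natural killer (NK) cell function is controlled by interactions between
killer-cell immunoglobulin-like receptors (KIR; a variable-gene-content
family on chromosome 19) and polymorphic HLA class I ligands (chromosome 6).
To a first approximation, KIR read four mutually exclusive HLA epitopes:
A3/11 (KIR3DL2), Bw4 (KIR3DL1), and C1/C2 (KIR2DL2/3 and KIR2DL1/2DS1).
Population studies of this system ask whether the frequency spectra of
receptor and ligand variants bear the signature of balancing selection, and
whether the two unlinked loci co-evolve — i.e. whether receptor and ligand
residue genotypes are correlated across individuals of one population.

`kirco` is an analysis pipeline for exactly this question, built to run on
mother-child cohort data and exercised end-to-end on synthetic cohorts with
known truth:

- **`kirco.nomenclature` / `kirco.io`** — KIR/HLA allele and haplotype-motif
  name parsing (`KIR3DL1*01502`, `cA01`, `B*53:01`), cohort genotype tables
  (TSV), aligned allele registries (FASTA), locus models (JSON); gene absence
  is the reserved allele `ABSENT`.
- **`kirco.simulate`** — synthetic mother-child cohorts: haplotype pools with
  configurable frequency spectra, Mendelian transmission with optional
  centromeric/telomeric crossover, latent fathers, and an optional planted
  coupling between an HLA residue group and a KIR residue group; emits truth
  files for every downstream stage.
- **`kirco.phasing`** — haplotype deduction by segregation in mother-child
  pairs, EM phasing (segregation counts as prior pseudo-counts) of unrelated
  individuals, and haplotype censuses: 2 haplotypes per independent
  individual (2N = 262 in the canonical 104-pair + 27-unrelated design),
  plus maternal non-transmitted haplotypes (2N = 366).
- **`kirco.ligands`** — sequence-based epitope assignment (Bw4 from the
  77–83 motif with Arg83 required; C1/C2 from HLA-C residue 80; A3/11 by
  name), a JSON interaction table with expression-null filtering, and the
  per-individual count of distinct viable receptor–ligand allotype pairs.
- **`kirco.selection`** — Tajima's D on gapped haplotype alignments with
  empirical two-tail p from a built-in Hudson-style coalescent under
  piecewise-constant demographies; Ewens–Watterson homozygosity F, Slatkin's
  exact test conditional on allele count k, and the normalized deviate
  F_nd = (F_obs − E[F]) / SD[F]; projection of allotypes onto binding-motif
  residue subsets so each motif is tested separately.
- **`kirco.diversity`** — Nei's unbiased heterozygosity, H_e = 1 − Σf²,
  mismatch distributions (p-distance, pairwise deletion), sliding-window
  mean-MAF profiles with percentile ranking, Hamming haplotype networks
  (MST plus alternative links, statistical-parsimony node probabilities),
  cumulative haplotype-frequency curves.
- **`kirco.coevolution`** — individual-by-individual p-distance matrices
  from phased residue genotypes, one-tailed Mantel permutation tests,
  multiallelic r²/D′, and the iterative residue-group scan: single HLA
  residues vs whole-gene KIR genotypes, then single KIR residues, then
  merging into LD groups (default: perfect LD) and group-vs-group re-testing
  until the ranking is stable.
- **`kirco.pipeline` / `kirco.cli`** — seed-deterministic orchestration of
  simulate → phase → ligands → selection → diversity → coevolve with a JSON
  manifest; `kirco run --seed 7 --outdir myrun` from the shell.

## Worked example

The analysis is a sequence of numbered drivers over the library:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_phase_haplotypes.py
python analysis/03_count_ligand_pairs.py
python analysis/04_selection_statistics.py
python analysis/05_haplotype_structure.py
python analysis/06_coevolution_scan.py
```

Running them prints, among other things:

```
KIR: 2N=262 (children+unrelated), 2N=366 (+maternal non-transmitted); k=20 haplotypes; truth recovery 131/131
worked example: 1 pair -> [('KIR2DL2*001', 'C*04:01')]
cohort of 235: mean 5.16 pairs, 95% interval [2.0, 9.0]
KIR: S=31 pi=21.66 D=9.123 p[constant]=0.0002 p[ancient_expansion]=0.0002
top-ranked pair: HLA-B (24, 45, 97) (perfect LD) x KIR3DL1/S1 (31, 44) (perfect LD), p=0.0149
```

Reading these: phasing recovers every simulated individual's haplotypes and
the census arithmetic gives the canonical 2N = 262 / 366 haplotype sets; the
worked one-pair compound genotype (homozygous A*23:01 / B*44:03 / C*04:01
with KIR2DL2\*001, no KIR2DL1/S1/S2, and non-expressed KIR3DL1\*004) yields
exactly the single KIR2DL2\*001 : C\*04:01 interaction; the balanced
haplotype pools produce strongly positive Tajima's D (an excess of
intermediate-frequency variants, the balancing-selection signature) that is
significant against 10,000 coalescent replicates; and the scan recovers the
planted coupling between the HLA-B residue trio 24/45/97 and the KIR3DL1 D0
pair 31/44, both reported as perfect-LD groups. Small tables land under
`results/`; bulky cohort files go to `scratch/`.

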