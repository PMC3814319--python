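"""Cohort, allele-registry and locus-model containers plus TSV/FASTA I/O.

External formats
----------------
Genotype table (TSV, header required)::

    individual_id  mother_id  gene  allele_1  allele_2

``mother_id`` is ``.`` for founders/unrelated individuals.  Gene absence is
encoded with the reserved allele name ``ABSENT``.

Allele registry (multi-FASTA)::

    >B*53:01 expressed=1
    ATG...

Sequences are aligned coding sequences in the gene's alignment frame; ``-`` is
the gap character.  Locus models and rule sets are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ABSENT = "ABSENT"

__all__ = [
    "ABSENT",
    "CohortValidationError",
    "GeneModel",
    "LocusModel",
    "AlleleRecord",
    "Registry",
    "Individual",
    "Cohort",
    "load_cohort",
    "save_cohort",
    "load_locus_models",
]


class CohortValidationError(ValueError):
    """An input table, registry or locus model failed validation."""


@dataclass(frozen=True)
class GeneModel:
    name: str
    framework: bool
    alignment_length: int
    leader_offset: int = 0  # leader-peptide codons removed for mature numbering


@dataclass(frozen=True)
class LocusModel:
    """Ordered gene list of one locus ("chromosome"), with a centromeric /
    telomeric split index used for crossover and per-region analyses."""

    locus_id: str
    genes: tuple[GeneModel, ...]
    cen_tel_boundary: int = 0  # genes[:b] centromeric, genes[b:] telomeric

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "cen_tel_boundary": self.cen_tel_boundary,
            "genes": [
                {"name": g.name, "framework": g.framework,
                 "alignment_length": g.alignment_length,
                 "leader_offset": g.leader_offset}
                for g in self.genes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocusModel":
        return cls(
            locus_id=d["locus_id"],
            genes=tuple(
                GeneModel(g["name"], bool(g["framework"]), int(g["alignment_length"]),
                          int(g.get("leader_offset", 0)))
                for g in d["genes"]
            ),
            cen_tel_boundary=int(d.get("cen_tel_boundary", 0)),
        )


@dataclass(frozen=True)
class AlleleRecord:
    """One allele: an aligned coding sequence and its derived protein.

    ``protein`` is in mature-protein numbering: the sequence is degapped,
    translated, and the first ``leader_offset`` residues are dropped.
    """

    gene: str
    name: str
    cds: str
    expressed: bool = True
    leader_offset: int = 0

    @cached_property
    def protein(self) -> str:
        if self.name == ABSENT:
            return ""
        coding = self.cds.replace("-", "")
        aa = str(Seq(coding).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        return aa[self.leader_offset:]

    def residue(self, position: int) -> str:
        """Residue at a mature-protein 1-based position, or '-' if absent/short."""
        prot = self.protein
        if position < 1 or position > len(prot):
            return "-"
        return prot[position - 1]


class Registry:
    """Mapping of allele name -> AlleleRecord for one or more genes.

    Absence is available for every known gene as a synthesised all-gap record
    named ``ABSENT``.
    """

    def __init__(self, records: list[AlleleRecord], locus_models: dict[str, LocusModel]):
        self._by_key: dict[tuple[str, str], AlleleRecord] = {}
        self._absent_cache: dict[str, AlleleRecord] = {}
        self._gene_len: dict[str, int] = {}
        self._gene_leader: dict[str, int] = {}
        for lm in locus_models.values():
            for g in lm.genes:
                self._gene_len[g.name] = g.alignment_length
                self._gene_leader[g.name] = g.leader_offset
        for r in records:
            if r.gene not in self._gene_len:
                raise CohortValidationError(f"allele {r.name}: unknown gene {r.gene}")
            if len(r.cds) != self._gene_len[r.gene]:
                raise CohortValidationError(
                    f"allele {r.name}: sequence length {len(r.cds)} != "
                    f"alignment length {self._gene_len[r.gene]} of {r.gene}"
                )
            key = (r.gene, r.name)
            if key in self._by_key and self._by_key[key].cds != r.cds:
                raise CohortValidationError(f"duplicate allele name {r.name} with differing cds")
            self._by_key[key] = r

    def get(self, gene: str, name: str) -> AlleleRecord:
        if name == ABSENT:
            if gene not in self._absent_cache:
                self._absent_cache[gene] = AlleleRecord(
                    gene, ABSENT, "-" * self._gene_len[gene], expressed=False)
            return self._absent_cache[gene]
        try:
            return self._by_key[(gene, name)]
        except KeyError:
            raise CohortValidationError(f"unknown allele {name!r} for gene {gene!r}") from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._by_key or key[1] == ABSENT

    def records(self) -> list[AlleleRecord]:
        return list(self._by_key.values())

    def alleles_of(self, gene: str) -> list[str]:
        return sorted(n for (g, n) in self._by_key if g == gene)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self._by_key == other._by_key and self._gene_len == other._gene_len


@dataclass
class Individual:
    id: str
    mother_id: str | None
    genotype: dict[str, tuple[str, ...]] = field(default_factory=dict)
    # genotype: gene -> sorted tuple of allele names (ABSENT allowed), size =
    # declared copy number (2 for the diploid loci modelled here)

    def alleles(self, gene: str) -> tuple[str, ...]:
        return self.genotype.get(gene, ())


@dataclass
class Cohort:
    """Individuals with unphased genotypes, pedigree links and the allele
    registry needed to interpret them."""

    locus_models: dict[str, LocusModel]
    registry: Registry
    individuals: list[Individual]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicated individual id(s): {dup}")
        known = set(ids)
        gene_locus = {g: lm.locus_id for lm in self.locus_models.values() for g in lm.gene_names}
        for ind in self.individuals:
            if ind.mother_id is not None and ind.mother_id not in known:
                raise CohortValidationError(
                    f"individual {ind.id}: mother id {ind.mother_id!r} not in cohort"
                )
            for gene, alleles in ind.genotype.items():
                if gene not in gene_locus:
                    raise CohortValidationError(f"individual {ind.id}: unknown gene {gene!r}")
                if len(alleles) != 2:
                    raise CohortValidationError(
                        f"individual {ind.id}, gene {gene}: expected a diploid pair, "
                        f"got {len(alleles)} entries"
                    )
                for a in alleles:
                    if (gene, a) not in self.registry:
                        raise CohortValidationError(
                            f"individual {ind.id}: unknown allele {a!r} for gene {gene}"
                        )

    def by_id(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    @property
    def mother_child_pairs(self) -> list[tuple[Individual, Individual]]:
        byid = {i.id: i for i in self.individuals}
        return [(byid[i.mother_id], i) for i in self.individuals if i.mother_id]

    @property
    def unrelated(self) -> list[Individual]:
        """Individuals that are neither children nor sampled mothers."""
        mothers = {i.mother_id for i in self.individuals if i.mother_id}
        return [i for i in self.individuals if i.mother_id is None and i.id not in mothers]

    def summary(self) -> dict:
        pairs = self.mother_child_pairs
        k_per_gene = {}
        for lm in self.locus_models.values():
            for g in lm.gene_names:
                seen = {a for ind in self.individuals for a in ind.alleles(g)}
                k_per_gene[g] = len(seen)
        return {
            "n_individuals": len(self.individuals),
            "n_pairs": len(pairs),
            "n_unrelated": len(self.unrelated),
            "k_alleles_per_gene": k_per_gene,
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            {k: v.to_dict() for k, v in self.locus_models.items()}
            == {k: v.to_dict() for k, v in other.locus_models.items()}
            and self.registry == other.registry
            and [(i.id, i.mother_id, i.genotype) for i in self.individuals]
            == [(i.id, i.mother_id, i.genotype) for i in other.individuals]
        )


def haplotype_sequence(registry: Registry, locus: LocusModel,
                       haplotype: tuple[str, ...], gene_slice: slice = slice(None),
                       ) -> str:
    """Gapped concatenated coding sequence of a haplotype (ABSENT genes
    contribute all-gap segments), optionally restricted to a gene range."""
    genes = locus.genes[gene_slice]
    alleles = haplotype[gene_slice]
    return "".join(registry.get(g.name, a).cds for g, a in zip(genes, alleles))


def load_locus_models(path: str | Path) -> dict[str, LocusModel]:
    with open(path) as fh:
        data = json.load(fh)
    models = [LocusModel.from_dict(d) for d in data["loci"]]
    return {m.locus_id: m for m in models}


def _read_registry_fasta(path: str | Path, locus_models: dict[str, LocusModel]) -> Registry:
    gene_of: dict[str, str] = {}
    leader: dict[str, int] = {}
    for lm in locus_models.values():
        for g in lm.genes:
            leader[g.name] = g.leader_offset
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        expressed = True
        for tok in rec.description.split()[1:]:
            if tok.startswith("expressed="):
                expressed = tok.split("=", 1)[1] == "1"
        gene = _gene_of_allele(name, locus_models)
        records.append(AlleleRecord(gene, name, str(rec.seq).upper(), expressed,
                                    leader.get(gene, 0)))
        gene_of[name] = gene
    return Registry(records, locus_models)


def _gene_of_allele(name: str, locus_models: dict[str, LocusModel]) -> str:
    """Resolve the registry gene an allele name belongs to (longest matching
    gene-name prefix; HLA names like B*53:01 match gene 'HLA-B' or 'B')."""
    candidates = [g for lm in locus_models.values() for g in lm.gene_names]
    prefix = name.split("*")[0]
    best = None
    for g in candidates:
        stem = g.removeprefix("HLA-")
        if prefix == g or prefix == stem or (g.endswith("/3") and prefix in (g[:-2] + "2", g[:-2] + "3")):
            best = g
        elif "/" in g:
            # composite loci such as KIR2DL2/3 or KIR3DL1/S1
            parts = g.split("/")
            head = parts[0]
            alts = [head] + [head[:-len(p)] + p for p in parts[1:]]
            if prefix in alts:
                best = g
    if best is None:
        raise CohortValidationError(f"allele {name!r} matches no gene in the locus models")
    return best


def load_cohort(genotype_table: str | Path, alleles: str | Path,
                locus_model: str | Path | dict[str, LocusModel]) -> Cohort:
    """Load and validate a cohort from the genotype TSV + registry FASTA +
    locus-model JSON; returns a fully validated :class:`Cohort`."""
    models = locus_model if isinstance(locus_model, dict) else load_locus_models(locus_model)
    registry = _read_registry_fasta(alleles, models)

    rows: list[tuple[str, str, str, tuple[str, ...]]] = []
    with open(genotype_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["individual_id", "mother_id", "gene"]
        if header[:3] != required:
            raise CohortValidationError(f"genotype table header must start with {required}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ind_id, mother, gene = parts[0], parts[1], parts[2]
            alleles_t = tuple(a for a in parts[3:] if a)
            rows.append((ind_id, mother, gene, alleles_t))

    inds: dict[str, Individual] = {}
    for ind_id, mother, gene, alleles_t in rows:
        ind = inds.setdefault(
            ind_id, Individual(ind_id, None if mother == "." else mother, {})
        )
        ind.genotype[gene] = tuple(sorted(alleles_t))
    return Cohort(models, registry, list(inds.values()))


def save_cohort(cohort: Cohort, genotype_table: str | Path, alleles: str | Path,
                locus_model: str | Path) -> None:
    """Write a cohort back to the genotype TSV / registry FASTA / locus JSON."""
    with open(locus_model, "w") as fh:
        json.dump({"loci": [m.to_dict() for m in cohort.locus_models.values()]}, fh, indent=1)
    recs = [
        SeqRecord(Seq(r.cds), id=r.name, description=f"expressed={int(r.expressed)}")
        for r in sorted(cohort.registry.records(), key=lambda r: (r.gene, r.name))
    ]
    SeqIO.write(recs, str(alleles), "fasta")
    gene_order = [g for lm in cohort.locus_models.values() for g in lm.gene_names]
    with open(genotype_table, "w") as fh:
        fh.write("individual_id\tmother_id\tgene\tallele_1\tallele_2\n")
        for ind in cohort.individuals:
            for gene in gene_order:
                if gene not in ind.genotype:
                    continue
                a = "\t".join(ind.genotype[gene])
                fh.write(f"{ind.id}\t{ind.mother_id or '.'}\t{gene}\t{a}\n")
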