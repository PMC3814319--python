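"""KIR epitope assignment and functional ligand-receptor pair counting.

HLA class I allotypes carry at most one of four mutually exclusive KIR
epitopes: A3/11 (a small subset of HLA-A, recognised by KIR3DL2), Bw4
(subsets of HLA-A and -B, recognised by KIR3DL1), and C1 / C2 (partitioning
the expressed HLA-C allotypes, recognised by KIR2DL2/3 and KIR2DL1/2DS1).
Bw4 is read from the 77-83 sequence motif and requires arginine 83; C1/C2
from residue 80 of HLA-C (Asn -> C1, Lys/other -> C2); A3/11 from the allele
name, because the KIR3DL2-binding determinants of HLA-A are not established.

An interaction table (JSON, additive rules with allotype-level exception
hooks and expression-null lists) maps receptor allotypes to the epitopes they
bind; the per-individual statistic is the number of distinct viable
(KIR allotype, HLA allotype) pairs carried, a phase-independent set count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .io import ABSENT, AlleleRecord, Cohort, Individual, Registry
from .nomenclature import allotype_name

__all__ = [
    "EpitopeConfig",
    "InteractionTable",
    "BindingSiteDefinition",
    "PairCountResult",
    "assign_epitopes",
    "count_functional_pairs",
    "cohort_pair_distribution",
    "load_default_epitope_config",
    "load_default_interaction_table",
    "load_default_binding_sites",
]

EPITOPES = ("A3/11", "Bw4", "C1", "C2")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("kirco").joinpath("data", name)))


@dataclass(frozen=True)
class EpitopeConfig:
    bw4_window: tuple[int, int]  # mature positions, inclusive
    bw4_patterns: tuple[str, ...]
    bw4_required_position: int
    bw4_required_residue: str
    c1_position: int
    c1_residue: str
    c1_name_exceptions: tuple[str, ...]  # HLA-B allotypes carrying C1
    a3_11_names: tuple[str, ...]  # allele-name first fields, e.g. A*03

    @classmethod
    def from_json(cls, path: str | Path) -> "EpitopeConfig":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            bw4_window=tuple(d["bw4"]["window"]),
            bw4_patterns=tuple(d["bw4"]["patterns"]),
            bw4_required_position=int(d["bw4"]["required_position"]),
            bw4_required_residue=d["bw4"]["required_residue"],
            c1_position=int(d["c1"]["position"]),
            c1_residue=d["c1"]["residue"],
            c1_name_exceptions=tuple(d["c1"].get("name_exceptions", [])),
            a3_11_names=tuple(d["a3_11"]["names"]),
        )


def load_default_epitope_config() -> EpitopeConfig:
    return EpitopeConfig.from_json(_data_path("epitope_rules.json"))


def assign_epitopes(allotype: AlleleRecord, rules: EpitopeConfig) -> frozenset[str]:
    """Epitope subset of one HLA class I allotype.

    C1 and C2 are mutually exclusive and exhaustive on expressed HLA-C; Bw4
    requires the configured 77-83 motif with Arg83; A3/11 is name-based.
    Gaps inside the epitope window raise (untyped epitope region).
    """
    gene = allotype.gene.removeprefix("HLA-")
    prot = allotype.protein
    name = allotype_name(allotype.name)
    out: set[str] = set()
    if gene == "C":
        res = allotype.residue(rules.c1_position)
        if res == "-":
            raise ValueError(f"{allotype.name}: untyped epitope region (position "
                             f"{rules.c1_position})")
        out.add("C1" if res == rules.c1_residue else "C2")
        return frozenset(out)
    if gene in ("A", "B"):
        if name in rules.c1_name_exceptions or name.split(":")[0] in rules.c1_name_exceptions:
            out.add("C1")
        lo, hi = rules.bw4_window
        if hi > len(prot):
            raise ValueError(f"{allotype.name}: protein does not cover the Bw4 window")
        window = prot[lo - 1:hi]
        if "-" in window or "X" in window:
            raise ValueError(f"{allotype.name}: untyped epitope region ({lo}-{hi})")
        req = allotype.residue(rules.bw4_required_position)
        if req == rules.bw4_required_residue and window in rules.bw4_patterns:
            out.add("Bw4")
        if gene == "A" and name.split(":")[0] in rules.a3_11_names:
            out.add("A3/11")
        return frozenset(out)
    raise ValueError(f"{allotype.name}: not an HLA class I gene ({allotype.gene})")


@dataclass
class InteractionTable:
    """Additive receptor->epitope rules with expression filtering.

    A pair (KIR allotype k, HLA allotype h) is viable when some rule whose
    receptor pattern matches k grants an epitope of h or names h explicitly,
    and neither allotype is on an expression-null list.
    """

    rules: list[dict] = field(default_factory=list)
    kir_nulls: frozenset[str] = frozenset()
    hla_nulls: frozenset[str] = frozenset()

    @classmethod
    def from_json(cls, path: str | Path) -> "InteractionTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(rules=d["rules"], kir_nulls=frozenset(d.get("kir_nulls", [])),
                   hla_nulls=frozenset(d.get("hla_nulls", [])))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"rules": self.rules, "kir_nulls": sorted(self.kir_nulls),
                       "hla_nulls": sorted(self.hla_nulls)}, fh, indent=1)

    def _matching_rules(self, kir_allotype: str) -> list[dict]:
        out = []
        for rule in self.rules:
            pat = rule["receptor"]
            if kir_allotype == pat or kir_allotype.startswith(pat + "*"):
                out.append(rule)
        return out

    def viable(self, kir_allotype: str, hla_allotype: str,
               hla_epitopes: frozenset[str]) -> bool:
        if kir_allotype in self.kir_nulls or hla_allotype in self.hla_nulls:
            return False
        rules = self._matching_rules(kir_allotype)
        if not rules:
            raise ValueError(f"KIR allotype {kir_allotype} missing from the "
                             "interaction table")
        for rule in rules:
            if hla_allotype in rule.get("hla_exceptions", ()):
                return True
            if hla_epitopes & set(rule.get("epitopes", ())):
                return True
        return False


def load_default_interaction_table() -> InteractionTable:
    return InteractionTable.from_json(_data_path("interaction_table.json"))


@dataclass
class PairCountResult:
    individual_id: str
    pairs: frozenset[tuple[str, str]]  # (KIR allotype, HLA allotype)

    @property
    def count(self) -> int:
        return len(self.pairs)


def _carried_allotypes(ind: Individual, registry: Registry,
                       prefix: str) -> dict[str, AlleleRecord]:
    """Distinct expressed allotypes of one receptor/ligand family carried by
    an individual (homozygous duplicates collapse; ABSENT and expression-null
    alleles drop)."""
    out: dict[str, AlleleRecord] = {}
    for gene, alleles in ind.genotype.items():
        if not gene.startswith(prefix):
            continue
        for a in alleles:
            if a == ABSENT:
                continue
            rec = registry.get(gene, a)
            if not rec.expressed:
                continue
            out.setdefault(allotype_name(a), rec)
    return out


def count_functional_pairs(ind: Individual, registry: Registry,
                           epitopes: EpitopeConfig,
                           table: InteractionTable) -> PairCountResult:
    """Distinct viable (KIR allotype, HLA allotype) pairs for one individual.

    Phase-independent: only the multiset of carried alleles matters, and set
    semantics make the count invariant to homozygosity.
    """
    kir = _carried_allotypes(ind, registry, "KIR")
    hla = _carried_allotypes(ind, registry, "HLA")
    hla_epi = {name: assign_epitopes(rec, epitopes) for name, rec in hla.items()}
    pairs = set()
    for k in kir:
        if k in table.kir_nulls:
            continue
        for h, epi in hla_epi.items():
            if table.viable(k, h, epi):
                pairs.add((k, h))
    return PairCountResult(ind.id, frozenset(pairs))


def cohort_pair_distribution(cohort: Cohort, epitopes: EpitopeConfig,
                             table: InteractionTable) -> dict:
    """Per-individual pair counts plus mean, central 95% empirical interval
    and a histogram over counts."""
    results = [count_functional_pairs(ind, cohort.registry, epitopes, table)
               for ind in cohort.individuals]
    counts = np.array([r.count for r in results])
    hist: dict[int, int] = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    lo, hi = np.percentile(counts, [2.5, 97.5])
    return {
        "per_individual": {r.individual_id: r.count for r in results},
        "pairs": {r.individual_id: sorted(r.pairs) for r in results},
        "mean": float(counts.mean()),
        "interval95": [float(lo), float(hi)],
        "histogram": dict(sorted(hist.items())),
    }


# ---------------------------------------------------------------------------
# Binding-site residue sets


@dataclass
class BindingSiteDefinition:
    """Named binding-motif residue sets per gene, in mature numbering, with
    derived exclusive sets (residues appearing in exactly one named site)."""

    sites: dict[str, dict[str, tuple[int, ...]]]  # gene -> site name -> residues

    @classmethod
    def from_json(cls, path: str | Path) -> "BindingSiteDefinition":
        with open(path) as fh:
            d = json.load(fh)
        return cls({g: {s: tuple(v) for s, v in sets.items()} for g, sets in d.items()})

    def exclusive_sets(self, gene: str) -> dict[str, tuple[int, ...]]:
        sets = self.sites[gene]
        counts: dict[int, int] = {}
        for residues in sets.values():
            for r in set(residues):
                counts[r] = counts.get(r, 0) + 1
        return {
            name: tuple(sorted(r for r in set(residues) if counts[r] == 1))
            for name, residues in sets.items()
        }

    def all_residues(self, gene: str) -> tuple[int, ...]:
        return tuple(sorted({r for s in self.sites[gene].values() for r in s}))


def load_default_binding_sites() -> BindingSiteDefinition:
    return BindingSiteDefinition.from_json(_data_path("binding_sites.json"))
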