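"""Haplotype deduction by mother-child segregation, EM phasing of the
remainder, and haplotype censuses.

Segregation first: the child's unphased genotype is split into every
gene-wise-consistent haplotype pair; a split survives when one of its
haplotypes could have been transmitted by the mother (its allele at every
gene occurs in the mother's genotype — ABSENT participates as an allele).
A child with exactly one surviving (maternal, paternal) assignment is
segregation-resolved, and the mother's phase follows by complement.
Ambiguous children and unrelated individuals are phased by a standard
haplotype-frequency EM over the consistent haplotype pairs, initialised
with the segregation-deduced haplotype counts as prior pseudo-counts; each
individual is then assigned its maximum-posterior pair (ties broken by the
lexicographically smallest pair).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .io import Cohort, Individual, LocusModel, Registry
from .nomenclature import allotype_name

Hap = tuple[str, ...]

__all__ = [
    "MendelianError",
    "PhasedIndividual",
    "HaplotypeCensus",
    "enumerate_splits",
    "segregation_phase",
    "em_phase",
    "phase_cohort",
    "haplotype_census",
]


class MendelianError(ValueError):
    """Mother and child genotypes admit no consistent transmission."""


@dataclass
class PhasedIndividual:
    id: str
    locus: str
    haplotypes: tuple[Hap, Hap]
    resolution: str  # "segregation" | "em" | "unresolved"
    maternal_index: int | None = None  # children: index of the maternal haplotype
    role: str = "unrelated"  # "child" | "mother" | "unrelated"
    nontransmitted: Hap | None = None  # mothers: the non-transmitted haplotype

    def __post_init__(self) -> None:
        a, b = self.haplotypes
        if len(a) != len(b):
            raise ValueError("haplotype length mismatch")


def enumerate_splits(genotype: dict[str, tuple[str, ...]],
                     genes: tuple[str, ...]) -> list[tuple[Hap, Hap]]:
    """All unordered splits of a diploid genotype into two haplotypes.

    Each gene contributes its allele pair in either orientation; the result
    is deduplicated and each pair canonically ordered (lexicographic).
    """
    for g in genes:
        if g not in genotype:
            raise ValueError(f"genotype missing gene {g}")
    het = [g for g in genes if genotype[g][0] != genotype[g][1]]
    out: set[tuple[Hap, Hap]] = set()
    for bits in itertools.product((0, 1), repeat=max(len(het) - 1, 0)):
        flip = dict(zip(het[1:], bits))
        h1, h2 = [], []
        for g in genes:
            a, b = genotype[g]
            if g in flip and flip[g]:
                a, b = b, a
            h1.append(a)
            h2.append(b)
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        out.add(pair)  # type: ignore[arg-type]
    return sorted(out)


def _compatible_with(hap: Hap, genotype: dict[str, tuple[str, ...]],
                     genes: tuple[str, ...]) -> bool:
    return all(a in genotype[g] for a, g in zip(hap, genes))


def _segregation_candidates(mgeno: dict[str, tuple[str, ...]],
                            cgeno: dict[str, tuple[str, ...]],
                            genes: tuple[str, ...]) -> set[tuple[Hap, Hap]]:
    """Ordered (maternal, paternal) assignments consistent with transmission."""
    candidates: set[tuple[Hap, Hap]] = set()
    for h1, h2 in enumerate_splits(cgeno, genes):
        if _compatible_with(h1, mgeno, genes):
            candidates.add((h1, h2))
        if h2 != h1 and _compatible_with(h2, mgeno, genes):
            candidates.add((h2, h1))
    return candidates


def segregation_phase(mother: Individual, child: Individual,
                      locus: LocusModel) -> tuple[PhasedIndividual, Hap]:
    """Phase a child against its mother; returns the phased child (maternal
    haplotype first) and the maternal transmitted haplotype.

    Raises :class:`MendelianError` (naming the offending gene) when no split
    is consistent; a child whose consistent assignments are not unique is
    returned with resolution ``"unresolved"``.
    """
    genes = locus.gene_names
    mgeno = {g: mother.genotype[g] for g in genes}
    cgeno = {g: child.genotype[g] for g in genes}
    candidates = _segregation_candidates(mgeno, cgeno, genes)
    if not candidates:
        for g in genes:
            if not set(cgeno[g]) & set(mgeno[g]):
                raise MendelianError(
                    f"child {child.id} shares no allele with mother "
                    f"{mother.id} at gene {g}")
        raise MendelianError(
            f"child {child.id}: no joint haplotype split is consistent with "
            f"mother {mother.id}")
    if len(candidates) == 1:
        (mat, pat), = candidates
        return (PhasedIndividual(child.id, locus.locus_id, (mat, pat),
                                 "segregation", maternal_index=0, role="child"),
                mat)
    pair = min(candidates)
    return (PhasedIndividual(child.id, locus.locus_id, pair, "unresolved",
                             maternal_index=None, role="child"), pair[0])


def _mother_phase(mother: Individual, transmitted: Hap,
                  locus: LocusModel) -> PhasedIndividual:
    other = []
    for g, a in zip(locus.gene_names, transmitted):
        pair = list(mother.genotype[g])
        pair.remove(a)
        other.append(pair[0])
    nontrans = tuple(other)
    haps = tuple(sorted((transmitted, nontrans)))
    return PhasedIndividual(mother.id, locus.locus_id, haps, "segregation",
                            role="mother", nontransmitted=nontrans)


def em_phase(genotypes: list[Individual], locus: LocusModel,
             priors: dict[Hap, float] | None = None, prior_weight: float = 1.0,
             max_iter: int = 200, tol: float = 1e-8,
             pair_constraints: dict[str, list[tuple[Hap, Hap]]] | None = None,
             ) -> tuple[dict[str, PhasedIndividual], dict[Hap, float], list[float]]:
    """Haplotype-frequency EM with prior pseudo-counts.

    ``pair_constraints`` restricts an individual's admissible unordered
    haplotype pairs (used for segregation-ambiguous children, whose pairs
    must stay consistent with their mothers).  Returns (phased individuals,
    final haplotype frequencies, penalized log-likelihood trace —
    non-decreasing by construction).
    """
    genes = locus.gene_names
    priors = priors or {}
    pair_constraints = pair_constraints or {}
    pairs_of: dict[str, list[tuple[Hap, Hap]]] = {}
    universe: dict[Hap, int] = {}

    def hid(h: Hap) -> int:
        return universe.setdefault(h, len(universe))

    for h in sorted(priors):
        hid(h)
    for ind in genotypes:
        if ind.id in pair_constraints:
            ps = sorted(pair_constraints[ind.id])
        else:
            missing = [g for g in genes if g not in ind.genotype]
            if missing:
                raise ValueError(
                    f"individual {ind.id}: genotype missing gene(s) {missing}")
            ps = enumerate_splits({g: ind.genotype[g] for g in genes}, genes)
        if not ps:
            raise ValueError(f"individual {ind.id}: no consistent haplotype pair")
        pairs_of[ind.id] = ps
        for a, b in ps:
            hid(a)
            hid(b)

    H = len(universe)
    haps = [None] * H
    for h, i in universe.items():
        haps[i] = h
    pseudo = np.zeros(H)
    for h, c in priors.items():
        pseudo[universe[h]] = c * prior_weight
    n_chrom = 2 * len(genotypes)
    freqs = (pseudo + 1.0)
    freqs = freqs / freqs.sum()

    loglik_trace: list[float] = []
    for _ in range(max_iter):
        expected = pseudo.copy()
        ll = float(np.sum(pseudo * np.log(np.maximum(freqs, 1e-300))))
        for ind in genotypes:
            ps = pairs_of[ind.id]
            w = np.array([
                (2.0 if a != b else 1.0) * freqs[universe[a]] * freqs[universe[b]]
                for a, b in ps
            ])
            tot = w.sum()
            ll += math.log(max(tot, 1e-300))
            w /= max(tot, 1e-300)
            for (a, b), wi in zip(ps, w):
                expected[universe[a]] += wi
                expected[universe[b]] += wi
        loglik_trace.append(ll)
        new = expected / expected.sum()
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new

    phased: dict[str, PhasedIndividual] = {}
    for ind in genotypes:
        ps = pairs_of[ind.id]
        w = [(2.0 if a != b else 1.0) * freqs[universe[a]] * freqs[universe[b]]
             for a, b in ps]
        # deterministic tie-break: among maximal posteriors, the
        # lexicographically smallest pair
        wmax = max(w)
        tied = [p for p, wi in zip(ps, w) if wi == wmax]
        pair = min(tied)
        phased[ind.id] = PhasedIndividual(ind.id, locus.locus_id, pair, "em",
                                          role="unrelated")
    freq_out = {haps[i]: float(f) for i, f in enumerate(freqs) if f > 0}
    return phased, freq_out, loglik_trace


def phase_cohort(cohort: Cohort, locus_id: str,
                 prior_weight: float = 1.0) -> dict[str, PhasedIndividual]:
    """Full phasing pass over one locus: segregation on mother-child pairs,
    then EM (segregation counts as priors) on unrelated individuals and any
    segregation-ambiguous children."""
    locus = cohort.locus_models[locus_id]
    genes = locus.gene_names
    phased: dict[str, PhasedIndividual] = {}
    priors: dict[Hap, float] = {}
    ambiguous: list[Individual] = []
    candidates_of: dict[str, set[tuple[Hap, Hap]]] = {}
    mothers = {m.id: m for m, _ in cohort.mother_child_pairs}
    for mother, child in cohort.mother_child_pairs:
        pc, transmitted = segregation_phase(mother, child, locus)
        if pc.resolution == "segregation":
            phased[child.id] = pc
            phased[mother.id] = _mother_phase(mother, transmitted, locus)
            for h in pc.haplotypes:
                priors[h] = priors.get(h, 0.0) + 1.0
        else:
            ambiguous.append(child)
            mgeno = {g: mother.genotype[g] for g in genes}
            cgeno = {g: child.genotype[g] for g in genes}
            candidates_of[child.id] = _segregation_candidates(mgeno, cgeno, genes)
    pool = cohort.unrelated + ambiguous
    if pool:
        constraints = {cid: sorted({tuple(sorted(c)) for c in cands})
                       for cid, cands in candidates_of.items()}
        em_res, _, _ = em_phase(pool, locus, priors, prior_weight,
                                pair_constraints=constraints)
        for ind in pool:
            pi = em_res[ind.id]
            if ind.mother_id is not None:
                pi.role = "child"
                # recover maternal orientation and phase the mother
                ordered = [c for c in candidates_of[ind.id]
                           if tuple(sorted(c)) == pi.haplotypes]
                if ordered:
                    mat, _ = min(ordered)
                    pi.maternal_index = pi.haplotypes.index(mat)
                    phased[ind.mother_id] = _mother_phase(
                        mothers[ind.mother_id], mat, locus)
            phased[ind.id] = pi
    return phased


# ---------------------------------------------------------------------------
# Censuses


@dataclass
class HaplotypeCensus:
    """Haplotype counts and frequencies for a chosen haplotype set."""

    locus: str
    counts: dict[Hap, float]
    level: str = "allele"

    @property
    def two_n(self) -> float:
        return sum(self.counts.values())

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> dict[Hap, float]:
        t = self.two_n
        return {h: c / t for h, c in self.counts.items()}

    def allotype_level(self, registry: Registry, locus: LocusModel,
                       ) -> "HaplotypeCensus":
        """Collapse synonymous variants (and expression-null alleles, which
        map to a per-gene null class) into allotype-level haplotypes."""
        out: dict[Hap, float] = {}
        for hap, c in self.counts.items():
            collapsed = []
            for g, a in zip(locus.gene_names, hap):
                if a != "ABSENT" and not registry.get(g, a).expressed:
                    collapsed.append(f"{g}*null")
                else:
                    collapsed.append(allotype_name(a))
            key = tuple(collapsed)
            out[key] = out.get(key, 0.0) + c
        return HaplotypeCensus(self.locus, out, level="allotype")


def haplotype_census(phased: dict[str, PhasedIndividual],
                     include_maternal_nontransmitted: bool = False,
                     ) -> HaplotypeCensus:
    """Census of independently segregating haplotypes.

    Default set: both haplotypes of every independent (non-mother)
    individual — children and unrelated (2N = 2 x n_independent); the flag
    adds each mother's non-transmitted haplotype
    (2N = 2 x n_independent + n_mothers).
    """
    if not phased:
        raise ValueError("empty phased set")
    counts: dict[Hap, float] = {}
    locus = next(iter(phased.values())).locus
    for pi in phased.values():
        if pi.role in ("child", "unrelated"):
            for h in pi.haplotypes:
                counts[h] = counts.get(h, 0.0) + 1.0
        elif pi.role == "mother" and include_maternal_nontransmitted:
            h = pi.nontransmitted
            if h is not None:
                counts[h] = counts.get(h, 0.0) + 1.0
    return HaplotypeCensus(locus, counts)
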