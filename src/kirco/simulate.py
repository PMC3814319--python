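"""Synthetic cohort generator.

Emulates the sampling design of a mother-child cohort typed for two unlinked
loci: a KIR-like locus with variable gene content (ABSENT is an allele) split
into centromeric and telomeric segments, and an HLA-like three-gene class I
locus.  Mothers and unrelated individuals are drawn as two independent
haplotypes from a configurable pool; each child receives one maternal
haplotype (optionally recombined at the cen/tel boundary) and one latent
paternal haplotype drawn from the pool.  Fathers are not emitted, matching a
design in which only mothers and newborns were sampled.

An optional receptor-ligand coupling biases the joint sampling of the two
loci by rejection at the individual level, so that the haplotype-pool
marginal frequencies are (approximately) preserved while the dosage of a
designated HLA residue class and a designated KIR residue class co-occur
more often than under independence.

All generator choices are stand-ins for an undeposited real cohort; the
manifest labels them as such.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (ABSENT, AlleleRecord, Cohort, GeneModel, Individual,
                 LocusModel, Registry, save_cohort)
from .selection import DemographicModel, coalescent_sample_spectrum, ewens_theta_for_k

__all__ = [
    "Coupling",
    "LocusPool",
    "SimConfig",
    "TruthSet",
    "sample_spectrum",
    "simulate_cohort",
    "plant_coupling",
    "default_sim_config",
    "phasing_benchmark_config",
    "coupling_demo_config",
    "write_outputs",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one fixed codon per amino acid keeps cds <-> protein deterministic
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

BW4_WINDOW = "NLRIALR"  # 77-83, Arg83
BW6_WINDOW = "SLRNLRG"

# residue-class membership used when stratifying lean pools
_KIR_D0_CLASS1 = ("KIR3DL1*002", "KIR3DL1*004", "KIR3DS1*013")
_HLA_B_TRIO1_LEAN = ("B*53:01", "B*58:01", "B*42:01")


def _protein_to_cds(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


@dataclass(frozen=True)
class Coupling:
    """Planted frequency coupling between an HLA residue set and a KIR
    residue set; strength in [0, 1] is the rejection probability for
    dosage-mismatched individuals (0 reproduces independence)."""

    hla_gene: str
    hla_residues: tuple[int, ...]
    kir_gene: str
    kir_residues: tuple[int, ...]
    strength: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")


@dataclass
class LocusPool:
    locus: LocusModel
    haplotypes: list[tuple[str, ...]]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) == 0:
            raise ValueError("empty haplotype pool")
        if len(self.haplotypes) != self.frequencies.size:
            raise ValueError("pool haplotypes and frequencies differ in length")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("pool frequencies must sum to 1")


@dataclass
class SimConfig:
    seed: int
    kir_pool: LocusPool
    hla_pool: LocusPool
    registry_records: list[AlleleRecord]
    n_pairs: int = 104
    n_unrelated: int = 27
    recomb_rate: float = 0.0
    coupling: Coupling | None = None
    spectrum_mode: str = "balanced"

    @property
    def locus_models(self) -> dict[str, LocusModel]:
        return {self.kir_pool.locus.locus_id: self.kir_pool.locus,
                self.hla_pool.locus.locus_id: self.hla_pool.locus}

    def registry(self) -> Registry:
        return Registry(self.registry_records, self.locus_models)


@dataclass
class TruthSet:
    """True phased haplotypes per individual and locus (for children index 0
    is the maternal haplotype), plus per-individual true functional pair
    counts when the default interaction configuration applies."""

    haplotypes: dict[str, dict[str, tuple[tuple[str, ...], tuple[str, ...]]]]
    pair_counts: dict[str, int] | None
    coupling: Coupling | None


# ---------------------------------------------------------------------------
# Frequency spectra for pools


def sample_spectrum(mode: str, k: int, n: int = 100,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample a frequency vector of k classes.

    balanced: symmetric Dirichlet with concentration 100 (near-even);
    directional: one dominant class with frequency > 0.85 by construction;
    neutral_coalescent: class frequencies of one neutral constant-size
    coalescent replicate of sample size n, conditioned on k classes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k == 1:
        return np.array([1.0])
    if mode == "balanced":
        return rng.dirichlet(np.full(k, 100.0))
    if mode == "directional":
        dom = 0.86 + 0.11 * rng.random()
        rest = rng.dirichlet(np.ones(k - 1)) * (1.0 - dom)
        return np.concatenate([[dom], rest])
    if mode == "neutral_coalescent":
        theta = ewens_theta_for_k(n, k)
        model = DemographicModel.constant(theta, "spectrum")
        for _ in range(500):
            counts = coalescent_sample_spectrum(model, n, rng)
            if counts.size == k:
                return counts / counts.sum()
        raise RuntimeError(f"could not condition a neutral spectrum on k={k}")
    raise ValueError(f"unknown spectrum mode {mode!r}")


# ---------------------------------------------------------------------------
# Default synthetic loci and registries


def _make_gene_alleles(rng: np.random.Generator, gene: str, names: list[str],
                       length: int, overrides: dict[str, dict[int, str]] | None = None,
                       n_random_poly: int = 3, expressed: dict[str, bool] | None = None,
                       ) -> list[AlleleRecord]:
    """Build allele records for one gene: a common base protein, a few random
    polymorphic positions, and per-allele fixed residue overrides."""
    base = "".join(rng.choice(list(_AA), size=length))
    reserved = {p for ov in (overrides or {}).values() for p in ov}
    free = [p for p in range(1, length + 1) if p not in reserved]
    poly = sorted(rng.choice(free, size=n_random_poly, replace=False)) if n_random_poly else []
    records = []
    seen: set[str] = set()
    for name in names:
        prot = list(base)
        for p in poly:
            prot[p - 1] = rng.choice(list(_AA))
        for p, aa in (overrides or {}).get(name, {}).items():
            prot[p - 1] = aa
        s = "".join(prot)
        while s in seen:  # enforce distinct proteins
            p = int(rng.choice(poly or free))
            prot[p - 1] = rng.choice(list(_AA))
            s = "".join(prot)
        seen.add(s)
        records.append(AlleleRecord(gene, name, _protein_to_cds(s),
                                    expressed=(expressed or {}).get(name, True)))
    return records


def _window_overrides(window: str, start: int = 77) -> dict[int, str]:
    return {start + i: aa for i, aa in enumerate(window)}


_HLA_LEN = 350
_KIR_LEN = 300


def _hla_locus_model() -> LocusModel:
    genes = tuple(GeneModel(g, True, _HLA_LEN * 3) for g in ("HLA-A", "HLA-B", "HLA-C"))
    return LocusModel("HLA", genes, cen_tel_boundary=0)


def _kir_locus_model() -> LocusModel:
    names = ["KIR3DL3", "KIR2DL2/3", "KIR2DL1", "KIR2DL4", "KIR3DL1/S1", "KIR3DL2"]
    framework = {"KIR3DL3", "KIR2DL4", "KIR3DL2"}
    genes = tuple(GeneModel(g, g in framework, _KIR_LEN * 3) for g in names)
    return LocusModel("KIR", genes, cen_tel_boundary=3)


def _default_registry(rng: np.random.Generator, lean: bool = False,
                      ) -> list[AlleleRecord]:
    recs: list[AlleleRecord] = []
    # --- HLA ---------------------------------------------------------------
    bw4 = _window_overrides(BW4_WINDOW)
    bw6 = _window_overrides(BW6_WINDOW)
    if lean:
        a_names = ["A*02:01"]
        b_names = ["B*07:02", "B*15:03", "B*35:01", "B*42:01", "B*53:01", "B*58:01"]
        c_names = ["C*04:01", "C*07:01"]
    else:
        a_names = ["A*02:01", "A*03:01", "A*23:01", "A*30:01", "A*68:01", "A*74:01"]
        b_names = ["B*07:02", "B*15:03", "B*35:01", "B*44:03", "B*49:01",
                   "B*50:01", "B*53:01", "B*58:01"]
        c_names = ["C*02:10", "C*04:01", "C*06:02", "C*07:01", "C*08:02", "C*16:01"]
    a_over = {n: dict(bw6) for n in a_names}
    if "A*23:01" in a_over:
        a_over["A*23:01"] = dict(bw4)
    recs += _make_gene_alleles(rng, "HLA-A", a_names, _HLA_LEN, a_over,
                               n_random_poly=0 if lean else 3)
    # planted coupling trio at HLA-B 24/45/97 (perfect LD across the pool)
    trio0 = {24: "A", 45: "K", 97: "S"}
    trio1 = {24: "T", 45: "M", 97: "W"}
    bw4_b = {"B*53:01", "B*44:03", "B*49:01", "B*58:01"} if not lean else set()
    trio1_b = {"B*53:01", "B*58:01", "B*44:03"} if not lean else {"B*53:01", "B*58:01", "B*42:01"}
    b_over = {}
    for n in b_names:
        ov = dict(bw4 if n in bw4_b else bw6)
        ov.update(trio1 if n in trio1_b else trio0)
        b_over[n] = ov
    recs += _make_gene_alleles(rng, "HLA-B", b_names, _HLA_LEN, b_over,
                               n_random_poly=2)
    c1_c = {"C*07:01", "C*08:02", "C*16:01"}
    c_over = {n: {80: ("N" if n in c1_c else "K"), 14: ("R" if n == "C*07:01" else "G"),
                  49: ("A" if n == "C*04:01" else "E")} for n in c_names}
    recs += _make_gene_alleles(rng, "HLA-C", c_names, _HLA_LEN, c_over,
                               n_random_poly=0 if lean else 2)
    # --- KIR ---------------------------------------------------------------
    pair0 = {31: "H", 44: "P"}
    pair1 = {31: "Y", 44: "L"}
    k3dl1_names = ["KIR3DL1*001", "KIR3DL1*002", "KIR3DL1*004", "KIR3DL1*015",
                   "KIR3DS1*013"]
    k3dl1_over = {n: dict(pair1 if n in ("KIR3DL1*002", "KIR3DL1*004", "KIR3DS1*013")
                          else pair0) for n in k3dl1_names}
    recs += _make_gene_alleles(
        rng, "KIR3DL1/S1", k3dl1_names, _KIR_LEN, k3dl1_over,
        n_random_poly=1, expressed={"KIR3DL1*004": False})
    recs += _make_gene_alleles(
        rng, "KIR3DL3", [f"KIR3DL3*{i:03d}" for i in range(1, 2 if lean else 9)],
        _KIR_LEN, None, n_random_poly=0 if lean else 4)
    recs += _make_gene_alleles(
        rng, "KIR2DL2/3",
        ["KIR2DL3*001"] if lean else
        ["KIR2DL2*001", "KIR2DL2*003", "KIR2DL3*001", "KIR2DL3*002", "KIR2DL3*005"],
        _KIR_LEN, None, n_random_poly=0 if lean else 3)
    recs += _make_gene_alleles(
        rng, "KIR2DL1",
        ["KIR2DL1*003"] if lean else
        ["KIR2DL1*001", "KIR2DL1*002", "KIR2DL1*003", "KIR2DL1*004"],
        _KIR_LEN,
        None if lean else {n: ({154: "H", 163: "R", 182: "H", 216: "L", 245: "R"}
                               if n in ("KIR2DL1*001", "KIR2DL1*003")
                               else {154: "N", 163: "Q", 182: "R", 216: "P", 245: "C"})
              for n in ["KIR2DL1*001", "KIR2DL1*002", "KIR2DL1*003", "KIR2DL1*004"]},
        n_random_poly=0 if lean else 1)
    recs += _make_gene_alleles(
        rng, "KIR2DL4", [f"KIR2DL4*{i:03d}" for i in range(1, 2 if lean else 4)],
        _KIR_LEN, None, n_random_poly=0 if lean else 2)
    recs += _make_gene_alleles(
        rng, "KIR3DL2", [f"KIR3DL2*{i:03d}" for i in range(1, 2 if lean else 6)],
        _KIR_LEN, None, n_random_poly=0 if lean else 3)
    return recs


def _build_pools(rng: np.random.Generator, records: list[AlleleRecord],
                 n_kir: int, n_hla: int, spectrum_mode: str,
                 lean: bool = False) -> tuple[LocusPool, LocusPool]:
    kir_lm = _kir_locus_model()
    hla_lm = _hla_locus_model()
    by_gene: dict[str, list[AlleleRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)

    def names(gene: str, pred=None) -> list[str]:
        return [r.name for r in by_gene[gene] if pred is None or pred(r.name)]

    kir_haps: list[tuple[str, ...]] = []
    attempts = 0
    while len(kir_haps) < n_kir and attempts < 50 * n_kir:
        attempts += 1
        cen_a = rng.random() < 0.53
        tel_a = rng.random() < 0.86
        if lean:
            # alternate the KIR3DL1 D0 31/44 class so a planted coupling
            # always segregates at intermediate frequency
            d0_class1 = len(kir_haps) % 2 == 1
            k3dl1 = rng.choice(names("KIR3DL1/S1",
                                     lambda n: (n in _KIR_D0_CLASS1) == d0_class1))
        else:
            k3dl1 = rng.choice(names("KIR3DL1/S1",
                                     lambda n: n.startswith("KIR3DL1") == tel_a)
                               or names("KIR3DL1/S1"))
        h = {
            "KIR3DL3": rng.choice(names("KIR3DL3")),
            "KIR2DL2/3": rng.choice(names("KIR2DL2/3",
                                          lambda n: n.startswith("KIR2DL3") == cen_a)
                                    or names("KIR2DL2/3")),
            "KIR2DL1": (rng.choice(names("KIR2DL1")) if (cen_a or rng.random() < 0.5 or lean)
                        else ABSENT),
            "KIR2DL4": rng.choice(names("KIR2DL4")) if (rng.random() > 0.03 or lean) else ABSENT,
            "KIR3DL1/S1": k3dl1,
            "KIR3DL2": rng.choice(names("KIR3DL2")) if (tel_a or rng.random() > 0.3 or lean)
                       else ABSENT,
        }
        hap = tuple(h[g] for g in kir_lm.gene_names)
        if hap not in kir_haps:
            kir_haps.append(hap)

    hla_haps: list[tuple[str, ...]] = []
    attempts = 0
    while len(hla_haps) < n_hla and attempts < 50 * n_hla:
        attempts += 1
        if lean:
            trio1 = len(hla_haps) % 2 == 1
            b = rng.choice(names("HLA-B", lambda n: (n in _HLA_B_TRIO1_LEAN) == trio1))
            hap = tuple(b if g == "HLA-B" else rng.choice(names(g))
                        for g in hla_lm.gene_names)
        else:
            hap = tuple(rng.choice(names(g)) for g in hla_lm.gene_names)
        if hap not in hla_haps:
            hla_haps.append(hap)

    kir_f = sample_spectrum(spectrum_mode, len(kir_haps), seed=rng)
    hla_f = sample_spectrum(spectrum_mode, len(hla_haps), seed=rng)
    return (LocusPool(kir_lm, kir_haps, kir_f), LocusPool(hla_lm, hla_haps, hla_f))


def default_sim_config(seed: int, n_pairs: int = 104, n_unrelated: int = 27,
                       n_kir_haplotypes: int = 20, n_hla_haplotypes: int = 20,
                       spectrum_mode: str = "balanced",
                       recomb_rate: float = 0.0) -> SimConfig:
    """Study-shaped synthetic configuration: 104 mother-child pairs plus 27
    unrelated individuals, balanced haplotype pools over a 6-gene KIR-like
    locus and a 3-gene HLA-like locus."""
    rng = np.random.default_rng(seed)
    records = _default_registry(rng)
    kir_pool, hla_pool = _build_pools(rng, records, n_kir_haplotypes,
                                      n_hla_haplotypes, spectrum_mode)
    return SimConfig(seed=seed, kir_pool=kir_pool, hla_pool=hla_pool,
                     registry_records=records, n_pairs=n_pairs,
                     n_unrelated=n_unrelated, recomb_rate=recomb_rate,
                     spectrum_mode=spectrum_mode)


def phasing_benchmark_config(seed: int) -> SimConfig:
    """20-haplotype pools (haplotype heterozygosity >= 0.9), 100 pairs + 27
    unrelated, no cen/tel recombination — the phasing truth-recovery setting."""
    return default_sim_config(seed, n_pairs=100, n_unrelated=27,
                              n_kir_haplotypes=20, n_hla_haplotypes=20,
                              recomb_rate=0.0)


def coupling_demo_config(seed: int, n: int = 200, strength: float = 0.5) -> SimConfig:
    """Unrelated cohort of n individuals with a planted coupling between the
    HLA-B residue trio (24, 45, 97; perfect LD in the pool) and the
    KIR3DL1/S1 residue pair (31, 44; perfect LD in the pool)."""
    rng = np.random.default_rng(seed)
    records = _default_registry(rng, lean=True)
    kir_pool, hla_pool = _build_pools(rng, records, 8, 8, "balanced", lean=True)
    cfg = SimConfig(seed=seed, kir_pool=kir_pool, hla_pool=hla_pool,
                    registry_records=records, n_pairs=0, n_unrelated=n,
                    recomb_rate=0.0,
                    coupling=Coupling("HLA-B", (24, 45, 97), "KIR3DL1/S1",
                                      (31, 44), strength))
    return plant_coupling(cfg)


# ---------------------------------------------------------------------------
# Sampling


def _coupling_classes(pool: LocusPool, registry: Registry, gene: str,
                      residues: tuple[int, ...]) -> np.ndarray:
    """Per-pool-haplotype binary class of the designated residue set."""
    gi = pool.locus.gene_names.index(gene)
    keys = []
    for hap in pool.haplotypes:
        rec = registry.get(gene, hap[gi])
        keys.append("".join(rec.residue(r) for r in residues))
    uniq = sorted(set(keys))
    if len(uniq) < 2:
        raise ValueError(f"coupling residue set {residues} on {gene} is "
                         "monomorphic in the pool; coupling undefined")
    if len(uniq) > 2:
        raise ValueError("coupling requires exactly two residue classes in the pool")
    return np.array([uniq.index(k) for k in keys])


def plant_coupling(cfg: SimConfig) -> SimConfig:
    """Validate the configured coupling against the pools (residue sets must
    be polymorphic) and return the activated configuration; strength 0
    reproduces independent sampling."""
    if cfg.coupling is None:
        raise ValueError("cfg.coupling is not set")
    registry = cfg.registry()
    _coupling_classes(cfg.hla_pool, registry, cfg.coupling.hla_gene,
                      cfg.coupling.hla_residues)
    _coupling_classes(cfg.kir_pool, registry, cfg.coupling.kir_gene,
                      cfg.coupling.kir_residues)
    return dataclasses.replace(cfg)


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, TruthSet]:
    """Draw the cohort; the seed fully determines the output."""
    rng = np.random.default_rng(cfg.seed)
    registry = cfg.registry()
    kir, hla = cfg.kir_pool, cfg.hla_pool
    b = kir.locus.cen_tel_boundary

    hla_cls = kir_cls = None
    strength = 0.0
    if cfg.coupling is not None and cfg.coupling.strength > 0:
        hla_cls = _coupling_classes(hla, registry, cfg.coupling.hla_gene,
                                    cfg.coupling.hla_residues)
        kir_cls = _coupling_classes(kir, registry, cfg.coupling.kir_gene,
                                    cfg.coupling.kir_residues)
        strength = cfg.coupling.strength

    def draw(pool: LocusPool) -> int:
        return int(rng.choice(len(pool.haplotypes), p=pool.frequencies))

    def match(hla_idx: tuple[int, int], kir_idx: tuple[int, int]) -> bool:
        return (hla_cls[hla_idx[0]] + hla_cls[hla_idx[1]]
                == kir_cls[kir_idx[0]] + kir_cls[kir_idx[1]])

    def draw_individual() -> tuple[tuple[int, int], tuple[int, int]]:
        while True:
            hi = (draw(hla), draw(hla))
            ki = (draw(kir), draw(kir))
            if strength == 0 or match(hi, ki) or rng.random() > strength:
                return hi, ki

    def crossover(h_keep: tuple[str, ...], h_other: tuple[str, ...]) -> tuple[str, ...]:
        if cfg.recomb_rate > 0 and rng.random() < cfg.recomb_rate:
            return h_keep[:b] + h_other[b:]
        return h_keep

    individuals: list[Individual] = []
    truth: dict[str, dict[str, tuple]] = {}

    def add(ind_id: str, mother_id: str | None,
            hla_pair: tuple[tuple[str, ...], tuple[str, ...]],
            kir_pair: tuple[tuple[str, ...], tuple[str, ...]]) -> None:
        geno: dict[str, tuple[str, ...]] = {}
        for lm, pair in ((hla.locus, hla_pair), (kir.locus, kir_pair)):
            for gi, gene in enumerate(lm.gene_names):
                geno[gene] = tuple(sorted((pair[0][gi], pair[1][gi])))
        individuals.append(Individual(ind_id, mother_id, geno))
        truth[ind_id] = {hla.locus.locus_id: hla_pair, kir.locus.locus_id: kir_pair}

    mothers: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for m in range(cfg.n_pairs):
        hi, ki = draw_individual()
        mothers.append((hi, ki))
        add(f"M{m + 1:03d}", None,
            (hla.haplotypes[hi[0]], hla.haplotypes[hi[1]]),
            (kir.haplotypes[ki[0]], kir.haplotypes[ki[1]]))
    for m, (hi, ki) in enumerate(mothers):
        # maternal transmitted haplotypes (independent choice per locus)
        mh = rng.integers(2)
        mk = rng.integers(2)
        mat_hla = hla.haplotypes[hi[mh]]
        mat_kir = crossover(kir.haplotypes[ki[mk]], kir.haplotypes[ki[1 - mk]])
        while True:
            ph, pk = draw(hla), draw(kir)
            if strength == 0:
                break
            # child's class dosages under the candidate paternal draw
            hd = (hla_cls[hi[mh]] + hla_cls[ph])
            kd = (kir_cls[ki[mk]] + kir_cls[pk])
            if hd == kd or rng.random() > strength:
                break
        add(f"C{m + 1:03d}", f"M{m + 1:03d}",
            (mat_hla, hla.haplotypes[ph]), (mat_kir, kir.haplotypes[pk]))
    for u in range(cfg.n_unrelated):
        hi, ki = draw_individual()
        add(f"U{u + 1:03d}", None,
            (hla.haplotypes[hi[0]], hla.haplotypes[hi[1]]),
            (kir.haplotypes[ki[0]], kir.haplotypes[ki[1]]))

    cohort = Cohort(cfg.locus_models, registry, individuals,
                    meta={"generator": "kirco.simulate", "seed": cfg.seed,
                          "synthetic": True})
    pair_counts = _truth_pair_counts(cohort)
    return cohort, TruthSet(truth, pair_counts, cfg.coupling)


def _truth_pair_counts(cohort: Cohort) -> dict[str, int] | None:
    from .ligands import (cohort_pair_distribution, load_default_epitope_config,
                          load_default_interaction_table)
    try:
        dist = cohort_pair_distribution(cohort, load_default_epitope_config(),
                                        load_default_interaction_table())
        return {k: int(v) for k, v in dist["per_individual"].items()}
    except (ValueError, KeyError):
        return None


# ---------------------------------------------------------------------------
# Emission


def write_outputs(cohort: Cohort, truth: TruthSet, cfg: SimConfig,
                  outdir: str | Path) -> dict[str, Path]:
    """Write genotype TSV + registry FASTA + locus JSON plus truth files and
    a manifest of the configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "alleles": outdir / "alleles.fasta",
        "locus_models": outdir / "locus_models.json",
        "truth_haplotypes": outdir / "truth_haplotypes.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "manifest": outdir / "manifest.json",
    }
    save_cohort(cohort, paths["genotypes"], paths["alleles"], paths["locus_models"])
    with open(paths["truth_haplotypes"], "w") as fh:
        fh.write("individual_id\tlocus\thap_index\talleles\n")
        for ind_id, loci in truth.haplotypes.items():
            for locus, pair in loci.items():
                for idx, hap in enumerate(pair):
                    fh.write(f"{ind_id}\t{locus}\t{idx}\t{','.join(hap)}\n")
    with open(paths["truth_pairs"], "w") as fh:
        fh.write("individual_id\tpair_count\n")
        for ind_id, c in (truth.pair_counts or {}).items():
            fh.write(f"{ind_id}\t{c}\n")
    manifest = {
        "note": "fully synthetic stand-in cohort; all generator choices are "
                "stand-ins for an undeposited study population",
        "seed": cfg.seed,
        "n_pairs": cfg.n_pairs,
        "n_unrelated": cfg.n_unrelated,
        "recomb_rate": cfg.recomb_rate,
        "spectrum_mode": cfg.spectrum_mode,
        "coupling": dataclasses.asdict(cfg.coupling) if cfg.coupling else None,
        "kir_pool": {"haplotypes": [list(h) for h in cfg.kir_pool.haplotypes],
                     "frequencies": cfg.kir_pool.frequencies.tolist()},
        "hla_pool": {"haplotypes": [list(h) for h in cfg.hla_pool.haplotypes],
                     "frequencies": cfg.hla_pool.frequencies.tolist()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return paths
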