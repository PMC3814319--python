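"""Receptor-ligand co-evolution statistics.

Builds individual-by-individual p-distance matrices from phased residue
genotypes (the two phased residue strings of an individual are concatenated
in canonical lexicographic order, making every statistic independent of the
phase representation), runs Mantel permutation tests of congruence between
matrices, computes multiallelic linkage-disequilibrium summaries (r², D′),
and performs the iterative residue-group scan: single ligand residues
against whole receptor-gene genotypes, then single receptor residues, then
merging of residues into LD groups and group-against-group re-testing until
the ranking is stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import LocusModel, Registry
from .phasing import PhasedIndividual

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "ResidueGroup",
    "ScanHit",
    "residue_states",
    "polymorphic_residues",
    "residue_distance_matrix",
    "mantel_test",
    "ld_stats",
    "stage1_residue_scan",
    "coevolution_scan",
]


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if self.matrix.min() < 0 or self.matrix.max() > 1 + 1e-12:
            raise ValueError("p-distances must lie in [0, 1]")


@dataclass
class MantelResult:
    z: float
    p: float
    n_perm: int
    r: float = float("nan")  # Pearson correlation of the off-diagonal vectors
    # (scale-free companion of z; z itself is the raw cross-product sum)


@dataclass(frozen=True)
class ResidueGroup:
    gene: str
    positions: tuple[int, ...]
    min_r2: float
    representatives: tuple[str, ...] = ()

    @property
    def ld_class(self) -> str:
        if len(self.positions) == 1:
            return "single"
        return "perfect LD" if self.min_r2 >= 1.0 - 1e-12 else f"r2>={self.min_r2:.2f}"


@dataclass
class ScanHit:
    hla_group: ResidueGroup
    kir_group: ResidueGroup
    mantel: MantelResult
    p_bonferroni: float


# ---------------------------------------------------------------------------
# Residue states from phased individuals


def residue_states(phased: dict[str, PhasedIndividual], registry: Registry,
                   locus: LocusModel, gene: str,
                   positions: list[int]) -> tuple[tuple[str, ...], np.ndarray]:
    """Per-individual phased residue characters.

    Returns (individual ids sorted, array of shape (n, 2, len(positions)))
    of single characters; gene absence yields '-'.
    """
    gi = locus.gene_names.index(gene)
    ids = tuple(sorted(phased))
    out = np.empty((len(ids), 2, len(positions)), dtype="U1")
    for i, ind in enumerate(ids):
        for h in range(2):
            allele = phased[ind].haplotypes[h][gi]
            rec = registry.get(gene, allele)
            for p, pos in enumerate(positions):
                out[i, h, p] = rec.residue(pos)
    return ids, out


def polymorphic_residues(phased: dict[str, PhasedIndividual], registry: Registry,
                         locus: LocusModel, gene: str) -> list[int]:
    """Mature-protein positions with more than one state among the phased
    haplotypes (gene absence '-' counts as a state)."""
    gi = locus.gene_names.index(gene)
    alleles = sorted({pi.haplotypes[h][gi] for pi in phased.values() for h in (0, 1)})
    if len(alleles) < 2:
        return []
    recs = [registry.get(gene, a) for a in alleles]
    max_len = max(len(r.protein) for r in recs)
    if max_len == 0:
        return []
    poly = []
    for pos in range(1, max_len + 1):
        if len({r.residue(pos) for r in recs}) > 1:
            poly.append(pos)
    return poly


def _canonical_strings(states: np.ndarray) -> list[str]:
    """Concatenate each individual's two residue strings in lexicographic
    order (phase-representation independence)."""
    out = []
    for i in range(states.shape[0]):
        a = "".join(states[i, 0])
        b = "".join(states[i, 1])
        out.append(min(a, b) + max(a, b))
    return out


def residue_distance_matrix(phased: dict[str, PhasedIndividual],
                            registry: Registry, locus: LocusModel, gene: str,
                            positions: list[int] | None = None) -> DistanceMatrix:
    """p-distance matrix between individuals' phased residue genotypes at a
    residue subset (None = every polymorphic residue of the gene).

    Distance = differing positions / compared positions; positions where
    either individual carries a gap (gene absence) are excluded pairwise.
    """
    if positions is None:
        positions = polymorphic_residues(phased, registry, locus, gene)
    if not positions:
        raise ValueError(f"no variation at {gene} for the requested residues")
    ids, states = residue_states(phased, registry, locus, gene, positions)
    strings = _canonical_strings(states)
    arr = np.array([list(s) for s in strings])
    if np.all(arr == arr[0]):
        raise ValueError(f"no variation at {gene} for the requested residues")
    n = len(ids)
    gap = arr == "-"
    mat = np.zeros((n, n))
    for i in range(n):
        ok = ~gap[i] & ~gap[i + 1:]
        diff = (arr[i + 1:] != arr[i]) & ok
        ncomp = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(ncomp > 0, diff.sum(axis=1) / np.maximum(ncomp, 1), 0.0)
        mat[i, i + 1:] = d
        mat[i + 1:, i] = d
    return DistanceMatrix(ids, mat)


# ---------------------------------------------------------------------------
# Mantel test


def mantel_test(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 10000,
                seed: int | np.random.Generator = 0) -> MantelResult:
    """One-tailed (upper) Mantel permutation test.

    z = Σ_{i<j} A_ij B_ij; the labels of B are permuted jointly over rows and
    columns; p = (1 + #{z_perm >= z_obs}) / (1 + n_perm).
    """
    if A.labels != B.labels:
        raise ValueError("distance matrices must share labels in the same order")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(A.labels)
    iu0, iu1 = np.triu_indices(n, k=1)
    iu0 = iu0.astype(np.int32)
    iu1 = iu1.astype(np.int32)
    a = A.matrix[iu0, iu1]
    b = B.matrix
    bv = b[iu0, iu1]
    z_obs = float(np.sum(a * bv))
    sa, sb = a.std(), bv.std()
    r = float(np.corrcoef(a, bv)[0, 1]) if sa > 0 and sb > 0 else 0.0
    a32 = a.astype(np.float32)
    bflat = b.astype(np.float32).ravel()
    count = 0
    chunk = max(1, min(n_perm, 256))
    done = 0
    # float32 accumulation only ranks z_perm against z_obs; keep a small
    # epsilon so exact ties under permutation still count as >=
    thresh = np.float32(z_obs * (1 - 1e-6) - 1e-9)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.empty((m, n), dtype=np.int32)
        for i in range(m):
            perms[i] = rng.permutation(n)
        idx = perms[:, iu0] * np.int32(n) + perms[:, iu1]
        z_perm = bflat.take(idx.ravel()).reshape(m, -1) @ a32
        count += int(np.sum(z_perm >= thresh))
        done += m
    p = (1 + count) / (1 + n_perm)
    return MantelResult(z=z_obs, p=p, n_perm=n_perm, r=r)


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_stats(states_a: np.ndarray, states_b: np.ndarray) -> tuple[float, float]:
    """Multiallelic r² and D′ between two sites over phased haplotypes.

    Both statistics are allele-frequency-weighted averages of the per-allele-
    pair normalizations: r² = Σ p_i q_j r²_ij, D′ = Σ p_i q_j |D_ij| / D_max,ij.
    """
    a = np.asarray(states_a)
    b = np.asarray(states_b)
    if a.shape != b.shape:
        raise ValueError("site state vectors differ in length")
    alleles_a, ia = np.unique(a, return_inverse=True)
    alleles_b, ib = np.unique(b, return_inverse=True)
    if alleles_a.size < 2 or alleles_b.size < 2:
        raise ValueError("both sites must be polymorphic")
    n = a.size
    joint = np.zeros((alleles_a.size, alleles_b.size))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= n
    p = joint.sum(axis=1)
    q = joint.sum(axis=0)
    r2 = 0.0
    dprime = 0.0
    for i in range(alleles_a.size):
        for j in range(alleles_b.size):
            d = joint[i, j] - p[i] * q[j]
            denom = p[i] * (1 - p[i]) * q[j] * (1 - q[j])
            r2_ij = d * d / denom if denom > 0 else 0.0
            if d >= 0:
                dmax = min(p[i] * (1 - q[j]), (1 - p[i]) * q[j])
            else:
                dmax = min(p[i] * q[j], (1 - p[i]) * (1 - q[j]))
            dprime_ij = abs(d) / dmax if dmax > 0 else 0.0
            r2 += p[i] * q[j] * r2_ij
            dprime += p[i] * q[j] * dprime_ij
    return float(r2), float(dprime)


def _haplotype_site_states(states: np.ndarray, p: int) -> np.ndarray:
    """Flatten (n, 2, n_pos) phased states to per-haplotype states at one
    position index."""
    return states[:, :, p].reshape(-1)


# ---------------------------------------------------------------------------
# Iterative residue-group scan


def stage1_residue_scan(phased_hla: dict[str, PhasedIndividual],
                        phased_kir: dict[str, PhasedIndividual],
                        registry: Registry, hla_locus: LocusModel,
                        kir_locus: LocusModel, hla_genes: list[str],
                        kir_genes: list[str], n_perm: int = 1000,
                        seed: int | np.random.Generator = 0,
                        _matrix=None) -> dict[tuple[str, int], float]:
    """First scan round: each single polymorphic HLA residue against each
    whole-gene KIR genotype matrix; returns the best (minimum) Mantel p per
    HLA residue over the KIR genes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if _matrix is None:
        def _matrix(phased, locus, gene, positions=None):
            return residue_distance_matrix(phased, registry, locus, gene, positions)
    kir_gene_mats = {}
    for g in kir_genes:
        if polymorphic_residues(phased_kir, registry, kir_locus, g):
            kir_gene_mats[g] = _matrix(phased_kir, kir_locus, g)
    out: dict[tuple[str, int], float] = {}
    for g in hla_genes:
        for r in polymorphic_residues(phased_hla, registry, hla_locus, g):
            A = _matrix(phased_hla, hla_locus, g, [r])
            best_p = 1.0
            for kg, B in kir_gene_mats.items():
                res = mantel_test(A, B, n_perm,
                                  np.random.default_rng(rng.integers(2**31)))
                best_p = min(best_p, res.p)
            out[(g, r)] = best_p
    return out


def _group_by_ld(states: np.ndarray, positions: list[int],
                 threshold: float) -> list[tuple[tuple[int, ...], float]]:
    """Merge residues into connected components under pairwise r² >=
    threshold; returns (positions, min within-group pairwise r²) per group."""
    m = len(positions)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    r2mat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r2, _ = ld_stats(_haplotype_site_states(states, i),
                             _haplotype_site_states(states, j))
            r2mat[i, j] = r2mat[j, i] = r2
            if r2 >= threshold - 1e-12:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(m):
        comps.setdefault(find(i), []).append(i)
    out = []
    for idxs in comps.values():
        if len(idxs) == 1:
            out.append(((positions[idxs[0]],), 1.0))
        else:
            min_r2 = min(r2mat[i, j] for i in idxs for j in idxs if i < j)
            out.append((tuple(positions[i] for i in idxs), float(min_r2)))
    return sorted(out)


def coevolution_scan(phased_hla: dict[str, PhasedIndividual],
                     phased_kir: dict[str, PhasedIndividual],
                     registry: Registry, hla_locus: LocusModel,
                     kir_locus: LocusModel, hla_genes: list[str],
                     kir_genes: list[str], alpha: float = 0.05,
                     n_perm: int = 1000, seed: int = 0,
                     r2_threshold: float = 1.0, max_rounds: int = 10,
                     final_n_perm: int | None = None,
                     adjust: bool = False) -> list[ScanHit]:
    """Iterative Mantel scan for co-evolving residue groups.

    Stage 1: each polymorphic HLA residue against each whole-gene KIR
    genotype matrix; stage 2: significant HLA residues against single KIR
    residues; stage 3: residues merged into LD groups (default threshold 1.0
    = perfect LD); stage 4: group-vs-group tests, ranked by z, re-tested
    until the ranking is stable.  Deterministic under the seed.  An empty
    stage-1 significant set yields an empty result (logged, not an error).
    With ``adjust`` the stage gates use Bonferroni-adjusted alpha instead of
    raw alpha.
    """
    rng = np.random.default_rng(seed)
    final_n_perm = final_n_perm or n_perm

    _cache: dict[tuple, DistanceMatrix] = {}

    def matrix(phased, locus, gene, positions=None):
        key = (id(phased), gene, None if positions is None else tuple(positions))
        if key not in _cache:
            _cache[key] = residue_distance_matrix(phased, registry, locus,
                                                  gene, positions)
        return _cache[key]

    hla_poly = {g: polymorphic_residues(phased_hla, registry, hla_locus, g)
                for g in hla_genes}
    kir_poly = {g: polymorphic_residues(phased_kir, registry, kir_locus, g)
                for g in kir_genes}

    # Stage 1
    stage1 = stage1_residue_scan(phased_hla, phased_kir, registry, hla_locus,
                                 kir_locus, hla_genes, kir_genes,
                                 n_perm=n_perm, seed=rng, _matrix=matrix)
    gate1 = alpha / len(stage1) if (adjust and stage1) else alpha
    sig_hla = [(g, r) for (g, r), p in stage1.items() if p <= gate1]
    if not sig_hla:
        logger.info("coevolution scan: no stage-1 significant HLA residue")
        return []

    # Stage 2: significant HLA residues vs single KIR residues
    sig_kir: set[tuple[str, int]] = set()
    sig_hla2: set[tuple[str, int]] = set()
    n_stage2 = len(sig_hla) * sum(len(p) for p in kir_poly.values())
    gate2 = alpha / n_stage2 if (adjust and n_stage2) else alpha
    for g, r in sig_hla:
        A = matrix(phased_hla, hla_locus, g, [r])
        for kg, positions in kir_poly.items():
            for kr in positions:
                B = matrix(phased_kir, kir_locus, kg, [kr])
                res = mantel_test(A, B, n_perm,
                                  np.random.default_rng(rng.integers(2**31)))
                if res.p <= gate2:
                    sig_kir.add((kg, kr))
                    sig_hla2.add((g, r))
    if not sig_kir:
        logger.info("coevolution scan: no stage-2 significant KIR residue")
        return []

    # Stage 3: LD groups per gene.  Significant residues are first expanded
    # with any residue of the same gene in r² >= threshold LD with one of
    # them (residues in LD that contribute to the correlation), which makes
    # the groups robust to borderline single-residue permutation noise.
    def expand_by_ld(phased, locus, poly: dict[str, list[int]],
                     sig: set[tuple[str, int]]) -> set[tuple[str, int]]:
        out = set(sig)
        for g, positions in poly.items():
            sig_pos = sorted(r for gg, r in sig if gg == g)
            if not sig_pos or len(positions) <= len(sig_pos):
                continue
            _, states = residue_states(phased, registry, locus, g, positions)
            idx = {r: i for i, r in enumerate(positions)}
            for r in positions:
                if (g, r) in out:
                    continue
                for sr in sig_pos:
                    r2, _ = ld_stats(_haplotype_site_states(states, idx[r]),
                                     _haplotype_site_states(states, idx[sr]))
                    if r2 >= r2_threshold - 1e-12:
                        out.add((g, r))
                        break
        return out

    sig_hla2 = expand_by_ld(phased_hla, hla_locus, hla_poly, sig_hla2)
    sig_kir = expand_by_ld(phased_kir, kir_locus, kir_poly, sig_kir)

    def build_groups(phased, locus, sig: set[tuple[str, int]]) -> list[ResidueGroup]:
        groups = []
        for g in sorted({gene for gene, _ in sig}):
            positions = sorted(r for gene, r in sig if gene == g)
            _, states = residue_states(phased, registry, locus, g, positions)
            for pos_tuple, min_r2 in _group_by_ld(states, positions, r2_threshold):
                gi = locus.gene_names.index(g)
                reps = tuple(sorted({pi.haplotypes[h][gi]
                                     for pi in phased.values() for h in (0, 1)})[:4])
                groups.append(ResidueGroup(g, pos_tuple, min_r2, reps))
        return groups

    hla_groups = build_groups(phased_hla, hla_locus, sig_hla2)
    kir_groups = build_groups(phased_kir, kir_locus, sig_kir)

    # Stage 4: group-vs-group, iterate until ranking stable
    prev_order: list[tuple] | None = None
    hits: list[ScanHit] = []
    for _ in range(max_rounds):
        hits = []
        n_tests = len(hla_groups) * len(kir_groups)
        for hg in hla_groups:
            A = matrix(phased_hla, hla_locus, hg.gene, list(hg.positions))
            for kg in kir_groups:
                B = matrix(phased_kir, kir_locus, kg.gene, list(kg.positions))
                res = mantel_test(A, B, final_n_perm,
                                  np.random.default_rng(rng.integers(2**31)))
                hits.append(ScanHit(hg, kg, res, min(1.0, res.p * n_tests)))
        # rank by the scale-free matrix correlation (z normalised for the
        # magnitude of the two matrices); tie-breaks are deterministic so the
        # ranking is independent of the permutation stream
        hits.sort(key=lambda h: (-h.mantel.r, h.hla_group.gene,
                                 h.hla_group.positions, h.kir_group.gene,
                                 h.kir_group.positions))
        order = [(h.hla_group.gene, h.hla_group.positions,
                  h.kir_group.gene, h.kir_group.positions) for h in hits]
        if order == prev_order:
            break
        prev_order = order
    else:
        logger.warning("coevolution scan: ranking did not stabilise in "
                       "%d rounds", max_rounds)
    return hits
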