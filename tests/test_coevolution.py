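import itertools

import numpy as np
import pytest

from kirco.coevolution import (DistanceMatrix, coevolution_scan, ld_stats,
                               mantel_test, residue_distance_matrix,
                               stage1_residue_scan)
from kirco.phasing import PhasedIndividual
from kirco.simulate import coupling_demo_config, simulate_cohort


def _phased_from_truth(truth, locus):
    return {pid: PhasedIndividual(pid, locus, tuple(sorted(loci[locus])),
                                  "segregation")
            for pid, loci in truth.haplotypes.items()}


@pytest.fixture(scope="module")
def coupled():
    cfg = coupling_demo_config(8, n=120, strength=0.6)
    cohort, truth = simulate_cohort(cfg)
    return (cohort, truth, _phased_from_truth(truth, "HLA"),
            _phased_from_truth(truth, "KIR"))


# --- distance matrices -------------------------------------------------------


class TestDistanceMatrix:
    def test_identical_homozygotes_distance_zero(self, coupled):
        cohort, truth, ph, _ = coupled
        hla = cohort.locus_models["HLA"]
        dm = residue_distance_matrix(ph, cohort.registry, hla, "HLA-B")
        ids = dm.labels
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if ph[a].haplotypes == ph[ids[j]].haplotypes:
                    assert dm.matrix[i, j] == 0.0

    def test_opposite_homozygotes_distance_one(self, coupled):
        cohort, truth, ph, _ = coupled
        hla = cohort.locus_models["HLA"]
        # two synthetic individuals homozygous for opposite trio classes
        classes = {}
        for pid, pi in ph.items():
            gi = hla.gene_names.index("HLA-B")
            a, b = pi.haplotypes[0][gi], pi.haplotypes[1][gi]
            rec = cohort.registry.get("HLA-B", a)
            if a == b:
                classes.setdefault(rec.residue(24), pid)
        if len(classes) == 2:
            p1, p2 = classes.values()
            dm = residue_distance_matrix(ph, cohort.registry, hla, "HLA-B",
                                         [24])
            i, j = dm.labels.index(p1), dm.labels.index(p2)
            assert dm.matrix[i, j] == 1.0

    def test_phase_swap_leaves_distances_unchanged(self, coupled):
        cohort, truth, ph, _ = coupled
        hla = cohort.locus_models["HLA"]
        swapped = {
            pid: PhasedIndividual(pid, "HLA",
                                  (pi.haplotypes[1], pi.haplotypes[0]),
                                  pi.resolution)
            for pid, pi in ph.items()}
        a = residue_distance_matrix(ph, cohort.registry, hla, "HLA-B")
        b = residue_distance_matrix(swapped, cohort.registry, hla, "HLA-B")
        assert np.array_equal(a.matrix, b.matrix)

    def test_monomorphic_selection_rejected(self, coupled):
        cohort, truth, ph, _ = coupled
        hla = cohort.locus_models["HLA"]
        with pytest.raises(ValueError, match="no variation"):
            residue_distance_matrix(ph, cohort.registry, hla, "HLA-A")

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.5], [0.4, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.1, 0.5], [0.5, 0.0]]))


# --- Mantel ------------------------------------------------------------------


def _random_dm(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(tuple(f"i{k}" for k in range(n)), m)


class TestMantel:
    def test_constant_matrix_gives_p_one(self, rng):
        a = _random_dm(rng, 8)
        c = np.full((8, 8), 0.5)
        np.fill_diagonal(c, 0.0)
        b = DistanceMatrix(a.labels, c)
        assert mantel_test(a, b, 200, rng).p == 1.0

    def test_label_mismatch_rejected(self, rng):
        a = _random_dm(rng, 5)
        b = _random_dm(rng, 6)
        with pytest.raises(ValueError):
            mantel_test(a, b, 10, rng)

    def test_mc_matches_exhaustive_at_n4(self, rng):
        a = _random_dm(rng, 4)
        b = _random_dm(rng, 4)
        iu = np.triu_indices(4, 1)
        z_obs = float(np.sum(a.matrix[iu] * b.matrix[iu]))
        count = 0
        for perm in itertools.permutations(range(4)):
            bp = b.matrix[np.ix_(perm, perm)]
            count += float(np.sum(a.matrix[iu] * bp[iu])) >= z_obs - 1e-12
        q = count / 24  # exact tail probability over the permutation group
        res = mantel_test(a, b, 4000, rng)
        se = np.sqrt(q * (1 - q) / 4000)
        assert abs(res.p - (1 + 4000 * q) / 4001) < 4 * se + 1e-6

    def test_z_invariant_under_joint_relabeling(self, rng):
        a = _random_dm(rng, 7)
        b = _random_dm(rng, 7)
        perm = rng.permutation(7)
        a2 = DistanceMatrix(tuple(a.labels[i] for i in perm),
                            a.matrix[np.ix_(perm, perm)])
        b2 = DistanceMatrix(a2.labels, b.matrix[np.ix_(perm, perm)])
        r1 = mantel_test(a, b, 10, rng)
        r2 = mantel_test(a2, b2, 10, rng)
        assert r1.z == pytest.approx(r2.z)


# --- LD ----------------------------------------------------------------------


class TestLD:
    def test_duplicated_site_in_full_ld(self):
        a = np.array(list("AATTAATT"))
        r2, dp = ld_stats(a, a.copy())
        assert r2 == pytest.approx(1.0)
        assert dp == pytest.approx(1.0)

    def test_toy_counts_hand_computed(self):
        # AB:40, Ab:10, aB:10, ab:40 -> D=0.15, r2=0.36, D'=0.6
        s1 = ["A"] * 50 + ["a"] * 50
        s2 = ["B"] * 40 + ["b"] * 10 + ["B"] * 10 + ["b"] * 40
        r2, dp = ld_stats(np.array(s1), np.array(s2))
        assert r2 == pytest.approx(0.36)
        assert dp == pytest.approx(0.6)

    def test_independent_sites_near_zero(self, rng):
        vals = []
        for _ in range(50):
            s1 = rng.choice(list("Aa"), size=400)
            s2 = rng.choice(list("Bb"), size=400)
            vals.append(ld_stats(s1, s2)[0])
        assert np.mean(vals) < 0.02

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_stats(np.array(["A"] * 4), np.array(list("BbBb")))


# --- the scan ----------------------------------------------------------------


class TestScan:
    def test_planted_group_recovered_and_labeled(self, coupled):
        cohort, truth, ph_h, ph_k = coupled
        hla = cohort.locus_models["HLA"]
        kir = cohort.locus_models["KIR"]
        hits = coevolution_scan(ph_h, ph_k, cohort.registry, hla, kir,
                                list(hla.gene_names), list(kir.gene_names),
                                n_perm=199, final_n_perm=999, seed=5)
        assert hits
        top = hits[0]
        assert top.hla_group.positions == (24, 45, 97)
        assert top.kir_group.positions == (31, 44)
        assert top.mantel.p <= 0.05
        assert top.hla_group.ld_class == "perfect LD"
        assert top.kir_group.ld_class == "perfect LD"

    def test_scan_is_deterministic_under_seed(self, coupled):
        cohort, truth, ph_h, ph_k = coupled
        hla = cohort.locus_models["HLA"]
        kir = cohort.locus_models["KIR"]
        runs = [coevolution_scan(ph_h, ph_k, cohort.registry, hla, kir,
                                 ["HLA-B"], ["KIR3DL1/S1"], n_perm=99, seed=3)
                for _ in range(2)]
        assert [(h.hla_group, h.kir_group, h.mantel.p) for h in runs[0]] == \
            [(h.hla_group, h.kir_group, h.mantel.p) for h in runs[1]]

    def test_uncoupled_cohort_usually_empty(self):
        cfg = coupling_demo_config(55, n=120, strength=0.0)
        cohort, truth = simulate_cohort(cfg)
        ph_h = _phased_from_truth(truth, "HLA")
        ph_k = _phased_from_truth(truth, "KIR")
        hla = cohort.locus_models["HLA"]
        kir = cohort.locus_models["KIR"]
        stage1 = stage1_residue_scan(ph_h, ph_k, cohort.registry, hla, kir,
                                     list(hla.gene_names),
                                     list(kir.gene_names), n_perm=199, seed=1)
        sig = sum(p <= 0.05 for p in stage1.values())
        assert sig <= max(2, 0.3 * len(stage1))
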