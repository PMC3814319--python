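import dataclasses

import numpy as np
import pytest

from kirco.io import ABSENT, Cohort, Individual
from kirco.examples import single_pair_individual
from kirco.ligands import (InteractionTable, assign_epitopes,
                           cohort_pair_distribution, count_functional_pairs,
                           load_default_binding_sites)


@pytest.fixture(scope="module")
def example():
    ind, registry, models = single_pair_individual()
    return ind, registry, models


def _record(registry, gene, name):
    return registry.get(gene, name)


class TestEpitopes:
    def test_bw4_distinguishes_b53_from_b35(self, example, epitope_config):
        _, registry, _ = example
        assert "Bw4" in assign_epitopes(_record(registry, "HLA-B", "B*53:01"),
                                        epitope_config)
        assert assign_epitopes(_record(registry, "HLA-B", "B*35:01"),
                               epitope_config) == frozenset()

    def test_c0401_is_c2(self, example, epitope_config):
        _, registry, _ = example
        assert assign_epitopes(_record(registry, "HLA-C", "C*04:01"),
                               epitope_config) == {"C2"}

    def test_hla_c_without_c1_is_c2(self, example, epitope_config):
        """Every expressed HLA-C allotype carries exactly one of C1/C2."""
        _, registry, _ = example
        for rec in registry.records():
            if rec.gene != "HLA-C":
                continue
            epi = assign_epitopes(rec, epitope_config)
            assert len(epi & {"C1", "C2"}) == 1

    def test_gap_in_window_is_untyped(self, example, epitope_config):
        _, registry, models = example
        rec = registry.get("HLA-B", ABSENT)
        with pytest.raises(ValueError, match="untyped|cover"):
            assign_epitopes(rec, epitope_config)


class TestPairCounting:
    def test_worked_example_single_pair(self, example, epitope_config,
                                        interaction_table):
        ind, registry, _ = example
        res = count_functional_pairs(ind, registry, epitope_config,
                                     interaction_table)
        assert res.count == 1
        assert res.pairs == {("KIR2DL2*001", "C*04:01")}

    def test_all_null_kir_gives_zero(self, example, epitope_config,
                                     interaction_table):
        ind, registry, _ = example
        geno = dict(ind.genotype)
        for g in list(geno):
            if g.startswith("KIR"):
                geno[g] = ("KIR3DL1*004", "KIR3DL1*004") if g == "KIR3DL1/S1" \
                    else (ABSENT, ABSENT)
        nulled = Individual("x", None, geno)
        res = count_functional_pairs(nulled, registry, epitope_config,
                                     interaction_table)
        assert res.count == 0

    def test_bw4_pair_via_expressed_kir3dl1(self, example, epitope_config,
                                            interaction_table):
        """Expressed KIR3DL1*001 with both B*53:01 (Bw4) and B*35:01 (not)
        yields exactly the one Bw4 pair."""
        ind, registry, _ = example
        geno = {g: (ABSENT, ABSENT) if g.startswith("KIR") else v
                for g, v in ind.genotype.items()}
        geno["KIR3DL1/S1"] = ("KIR3DL1*001", "KIR3DL1*001")
        geno["HLA-B"] = ("B*35:01", "B*53:01")
        geno["HLA-A"] = ("A*23:01", "A*23:01")  # Bw4 too -> second pair
        subject = Individual("y", None, geno)
        res = count_functional_pairs(subject, registry, epitope_config,
                                     interaction_table)
        assert ("KIR3DL1*001", "B*53:01") in res.pairs
        assert all(h != "B*35:01" for _, h in res.pairs)

    def test_phase_invariance_and_set_semantics(self, example, epitope_config,
                                                interaction_table):
        ind, registry, _ = example
        het = Individual("z", None, dict(ind.genotype))
        het.genotype["HLA-B"] = ("B*44:03", "B*53:01")
        base = count_functional_pairs(het, registry, epitope_config,
                                      interaction_table)
        flipped = Individual("z2", None, {
            g: tuple(reversed(v)) for g, v in het.genotype.items()})
        # unordered genotypes: allele order within the pair cannot matter
        assert count_functional_pairs(flipped, registry, epitope_config,
                                      interaction_table).pairs == base.pairs
        hom = Individual("z3", None, dict(het.genotype))
        hom.genotype["HLA-C"] = ("C*04:01", "C*04:01")
        assert count_functional_pairs(hom, registry, epitope_config,
                                      interaction_table).pairs == base.pairs

    def test_adding_rule_is_monotone(self, example, epitope_config,
                                     interaction_table):
        ind, registry, _ = example
        extended = InteractionTable(
            rules=interaction_table.rules + [
                {"receptor": "KIR3DL2", "epitopes": ["Bw4"]}],
            kir_nulls=interaction_table.kir_nulls,
            hla_nulls=interaction_table.hla_nulls)
        before = count_functional_pairs(ind, registry, epitope_config,
                                        interaction_table).count
        after = count_functional_pairs(ind, registry, epitope_config,
                                       extended).count
        assert after >= before

    def test_unknown_receptor_is_reported(self, example, epitope_config):
        ind, registry, _ = example
        empty = InteractionTable(rules=[])
        with pytest.raises(ValueError, match="missing from"):
            count_functional_pairs(ind, registry, epitope_config, empty)


class TestCohortDistribution:
    def test_clone_cohort_is_constant(self, example, epitope_config,
                                      interaction_table):
        ind, registry, models = example
        clones = [Individual(f"c{i}", None, dict(ind.genotype)) for i in range(6)]
        cohort = Cohort(models, registry, clones)
        dist = cohort_pair_distribution(cohort, epitope_config, interaction_table)
        assert dist["mean"] == 1.0
        assert dist["interval95"] == [1.0, 1.0]
        assert dist["histogram"] == {1: 6}

    def test_matches_truth_counts(self, small_cohort, epitope_config,
                                  interaction_table):
        cohort, truth = small_cohort
        dist = cohort_pair_distribution(cohort, epitope_config, interaction_table)
        assert dist["per_individual"] == truth.pair_counts

    def test_vacuous_table_gives_all_zero(self, small_cohort, epitope_config):
        cohort, _ = small_cohort
        vac = InteractionTable(rules=[
            {"receptor": g.split("/")[0][:8] if g.startswith("KIR") else g,
             "epitopes": []}
            for g in ("KIR3DL3", "KIR2DL2", "KIR2DL3", "KIR2DL1", "KIR2DL4",
                      "KIR3DL1", "KIR3DS1", "KIR3DL2")])
        dist = cohort_pair_distribution(cohort, epitope_config, vac)
        assert dist["mean"] == 0.0


def test_binding_sites_cover_coevolution_residues():
    sites = load_default_binding_sites()
    required = {
        "HLA-B": [24, 45, 77, 78, 79, 80, 81, 82, 83, 114, 194],
        "HLA-C": [14, 49, 194, 261, 273, 311, 313, 332, 345],
        "KIR3DL1": [31, 44, 86],
        "KIR2DL1": [154, 163, 182, 216, 245],
    }
    for gene, residues in required.items():
        have = set(sites.all_residues(gene))
        assert set(residues) <= have, gene


def test_exclusive_sets_are_pairwise_disjoint():
    sites = load_default_binding_sites()
    for gene in sites.sites:
        excl = sites.exclusive_sets(gene)
        names = list(excl)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not set(excl[a]) & set(excl[b])
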