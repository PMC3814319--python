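import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirco.selection import (DemographicModel, FrequencySpectrum,
                             coalescent_simulate, ewens_theta_for_k,
                             ewens_watterson_f, motif_project,
                             sample_ewens_configurations, slatkin_fnd,
                             tajima_constants, tajima_significance, tajimas_d)

# --- Tajima's D --------------------------------------------------------------


def _oracle_tajima(seqs):
    """Spreadsheet-style evaluation from first principles: direct pairwise
    difference counts and the published constants."""
    n = len(seqs)
    L = len(seqs[0])
    S = sum(1 for i in range(L) if len({s[i] for s in seqs}) > 1)
    pi = np.mean([sum(a != b for a, b in zip(s1, s2))
                  for s1, s2 in itertools.combinations(seqs, 2)])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
    return S, pi, (pi - S / a1) / math.sqrt(var)


def test_toy_alignment_matches_hand_evaluation():
    seqs = ["AAAA", "AAAT", "AATT", "ATTT"]
    S, pi, D = _oracle_tajima(seqs)
    res = tajimas_d(seqs)
    assert res.S == S == 3
    assert res.pi == pytest.approx(pi)
    assert res.D == pytest.approx(D)


def test_identical_sequences_flag_undefined_d():
    res = tajimas_d(["ACGT"] * 5)
    assert res.S == 0 and res.pi == 0
    assert not res.defined


def test_gap_sites_excluded_from_s_but_pairwise_in_pi():
    # site 4 has a gap -> excluded from S; pi compares it pairwise
    seqs = ["AAAA", "AATA", "AAT-", "AAAA"]
    res = tajimas_d(seqs)
    assert res.S == 1
    # pairs: (1,2)=1 (1,3)=1 (1,4)=0 (2,3)=0 (2,4)=1 (3,4)=1 -> mean 4/6
    assert res.pi == pytest.approx(4 / 6)


def test_constants_match_published_n10_values():
    c = tajima_constants(10)
    assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
    assert c["e1"] > 0 and c["e2"] > 0


# --- coalescent simulator ----------------------------------------------------


class TestCoalescent:
    def test_mean_pairwise_difference_matches_theta(self, rng):
        sims = coalescent_simulate(DemographicModel.constant(4.0), 2, 20000, rng)
        pis = np.array([r.pi for r in sims])
        se = pis.std() / np.sqrt(pis.size)
        assert abs(pis.mean() - 4.0) < 3 * se

    def test_mean_segregating_sites_matches_watterson(self, rng):
        sims = coalescent_simulate(DemographicModel.constant(5.0), 10, 5000, rng)
        Ss = np.array([r.S for r in sims])
        se = Ss.std() / np.sqrt(Ss.size)
        assert abs(Ss.mean() - 5.0 * tajima_constants(10)["a1"]) < 3 * se

    def test_recent_expansion_skews_d_negative(self, rng):
        model = DemographicModel("growth", ((0.0, 10.0), (0.05, 1.0)), 5.0)
        sims = coalescent_simulate(model, 30, 500, rng)
        ds = np.array([r.D for r in sims if r.defined])
        assert ds.mean() < 0

    def test_cross_check_against_msprime(self, rng):
        """Independent coalescent: msprime with matching time scaling must
        give the same mean S distributionally."""
        import msprime

        theta, n, reps = 3.0, 8, 400
        mine = coalescent_simulate(DemographicModel.constant(theta), n, reps, rng)
        s_mine = np.array([r.S for r in mine])
        s_ms = []
        for i in range(reps):
            ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                                      random_seed=10_000 + i)
            mts = msprime.sim_mutations(ts, rate=theta / 2,
                                        random_seed=20_000 + i,
                                        discrete_genome=False)
            s_ms.append(mts.num_sites)
        s_ms = np.array(s_ms)
        se = np.sqrt(s_mine.var() / reps + s_ms.var() / reps)
        assert abs(s_mine.mean() - s_ms.mean()) < 4 * se

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel("bad", ((0.1, 1.0),), 5.0)
        with pytest.raises(ValueError):
            DemographicModel("bad", ((0.0, 1.0), (0.0, 2.0)), 5.0)


class TestTajimaSignificance:
    def test_central_value_capped_at_one(self, rng):
        sims = coalescent_simulate(DemographicModel.constant(5.0), 20, 200, rng)
        ds = sorted(r.D for r in sims if r.defined)
        median = ds[len(ds) // 2]
        assert tajima_significance(median, sims) == 1.0

    def test_extreme_observation_rank_arithmetic(self, rng):
        sims = coalescent_simulate(DemographicModel.constant(5.0), 20, 999, rng)
        defined = [r for r in sims if r.defined]
        extreme = max(r.D for r in defined) + 10
        assert tajima_significance(extreme, defined) == \
            pytest.approx(2 / (len(defined) + 1))

    def test_invariant_under_simulation_order(self, rng):
        sims = coalescent_simulate(DemographicModel.constant(5.0), 20, 300, rng)
        p1 = tajima_significance(0.0, sims)
        p2 = tajima_significance(0.0, list(reversed(sims)))
        assert p1 == p2


# --- Ewens-Watterson / Slatkin ----------------------------------------------


def test_f_direct_evaluations():
    assert ewens_watterson_f(FrequencySpectrum.from_counts({"a": 7})) == 1.0
    even = FrequencySpectrum.from_counts({c: 5 for c in "abcd"})
    assert ewens_watterson_f(even) == pytest.approx(0.25)
    spec = FrequencySpectrum.from_counts({"a": 5, "b": 3, "c": 2})
    assert ewens_watterson_f(spec) == pytest.approx(0.38)


def test_f_plus_he_is_one():
    spec = FrequencySpectrum.from_counts({"a": 9, "b": 4, "c": 1})
    assert spec.F + spec.H_e == 1.0


def _ewens_conditional_exact(n, k):
    """Exhaustive oracle: integer partitions of n into k parts with the
    theta-free conditional Ewens weights 1 / (prod_j j^{a_j} a_j!)."""
    def partitions(n, k, mx):
        if k == 1:
            if n <= mx:
                yield (n,)
            return
        for first in range(min(n - k + 1, mx), 0, -1):
            for rest in partitions(n - first, k - 1, first):
                yield (first,) + rest

    weights = {}
    for part in partitions(n, k, n):
        a = {}
        for sz in part:
            a[sz] = a.get(sz, 0) + 1
        w = 1.0
        for j, aj in a.items():
            w /= (j ** aj) * math.factorial(aj)
        weights[part] = w
    tot = sum(weights.values())
    return {p: w / tot for p, w in weights.items()}


@pytest.mark.parametrize("n,k", [(5, 2), (6, 3), (8, 4), (8, 2), (7, 3)])
def test_conditional_sampler_matches_exhaustive_enumeration(n, k, rng):
    exact = _ewens_conditional_exact(n, k)
    theta = ewens_theta_for_k(n, k)
    got = {}
    accepted = 0
    while accepted < 4000:
        cfgs = sample_ewens_configurations(n, theta, 4000, rng)
        for cfg in cfgs:
            c = tuple(sorted((int(x) for x in cfg if x > 0), reverse=True))
            if len(c) == k:
                got[c] = got.get(c, 0) + 1
                accepted += 1
    total = sum(got.values())
    assert set(got) <= set(exact)
    for part, p in exact.items():
        phat = got.get(part, 0) / total
        se = math.sqrt(p * (1 - p) / total)
        assert abs(phat - p) < 4 * se + 1e-9, (part, p, phat)


def test_even_spectrum_has_negative_fnd(rng):
    spec = FrequencySpectrum.from_counts({c: 10 for c in "abcde"})
    res = slatkin_fnd(spec, n_sim=2000, seed=rng)
    assert res.F_nd < 0
    assert res.p_slatkin <= 0.2


def test_skewed_spectrum_has_positive_fnd(rng):
    spec = FrequencySpectrum.from_counts({"a": 46, "b": 2, "c": 1, "d": 1})
    res = slatkin_fnd(spec, n_sim=2000, seed=rng)
    assert res.F_nd > 0


def test_monomorphic_spectrum_flagged():
    res = slatkin_fnd(FrequencySpectrum.from_counts({"a": 30}))
    assert res.monomorphic
    assert math.isnan(res.F_nd)


# --- motif projection --------------------------------------------------------


class _Rec:
    def __init__(self, name, protein):
        self.name = name
        self.protein = protein

    def residue(self, pos):
        return self.protein[pos - 1] if 1 <= pos <= len(self.protein) else "-"


def test_projection_identity_on_all_residues():
    recs = [(_Rec("x", "ARND"), 10), (_Rec("y", "ARNE"), 5), (_Rec("z", "GRND"), 5)]
    spec = motif_project(recs, [1, 2, 3, 4])
    assert spec.k == 3
    assert spec.n == 20


def test_projection_merges_outside_differences():
    recs = [(_Rec("x", "ARND"), 10), (_Rec("y", "ARNE"), 5)]
    spec = motif_project(recs, [1, 2])
    assert spec.k == 1 and spec.monomorphic
    assert spec.n == 15


def test_projection_idempotent_and_commutes_with_restriction():
    recs = [(_Rec("x", "ARND"), 8), (_Rec("y", "GRNE"), 4), (_Rec("z", "GRLD"), 4)]
    spec_13 = motif_project(recs, [1, 3])
    classes = [(_Rec(v, v), c) for v, c in zip(spec_13.variants, spec_13.counts)]
    again = motif_project(classes, [1, 2])
    assert sorted(zip(again.variants, again.counts)) == \
        sorted(zip(spec_13.variants, spec_13.counts))


def test_projection_out_of_range_residue_rejected():
    with pytest.raises(ValueError, match="outside"):
        motif_project([(_Rec("x", "ARND"), 1)], [9])


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(1, 50), min_size=1, max_size=8))
def test_spectrum_invariants(counts):
    spec = FrequencySpectrum.from_counts({f"v{i}": c for i, c in enumerate(counts)})
    assert 1 / spec.k - 1e-12 <= spec.F <= 1.0
    assert spec.F + spec.H_e == pytest.approx(1.0)
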