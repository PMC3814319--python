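import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirco.diversity import (MarkerSeries, cumulative_haplotype_curve,
                             hamming_distance, hamming_network, he_ssf,
                             mismatch_distribution, nei_heterozygosity,
                             pairwise_p_distance, percentile_of_interval,
                             sliding_window_maf, templeton_node_probability)
from kirco.selection import FrequencySpectrum, ewens_watterson_f


# --- heterozygosity ----------------------------------------------------------


def test_nei_unbiased_direct_values():
    assert nei_heterozygosity(FrequencySpectrum.from_counts({"a": 9})) == 0.0
    spec = FrequencySpectrum.from_counts({"a": 5, "b": 5})
    assert nei_heterozygosity(spec) == pytest.approx(10 / 9 * 0.5)


def test_nei_at_least_plugin():
    spec = FrequencySpectrum.from_counts({"a": 7, "b": 2, "c": 1})
    assert nei_heterozygosity(spec) >= spec.H_e


def test_he_ssf_values_and_identity():
    assert he_ssf([1.0]) == 0.0
    assert he_ssf([0.5, 0.5]) == pytest.approx(0.5)
    spec = FrequencySpectrum.from_counts({"a": 3, "b": 2, "c": 5})
    assert he_ssf(spec.frequencies) == pytest.approx(1 - ewens_watterson_f(spec))


# --- mismatch distributions --------------------------------------------------


def test_identical_haplotypes_put_all_mass_at_zero():
    edges, counts, excl = mismatch_distribution(["ACGT"] * 4)
    assert counts.sum() == 6 and excl == 0
    assert counts[0] == 6


def test_pairwise_deletion_gap_toy():
    assert pairwise_p_distance("ACT-", "AC-G") == 0.0  # 2 comparable, equal
    assert pairwise_p_distance("TCT-", "AC-G") == pytest.approx(0.5)
    assert pairwise_p_distance("--", "AA") is None


def test_two_clade_fixture_is_bimodal():
    clade1 = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT"]
    clade2 = ["GGGGGGGGGG", "GGGGGGGGGC", "GGGGGGGGCC"]
    seqs = clade1 + clade2
    edges, counts, _ = mismatch_distribution(seqs, bin_width=0.1)
    # oracle: direct pair enumeration
    dists = [pairwise_p_distance(a, b) for a, b in itertools.combinations(seqs, 2)]
    assert counts.sum() == len(dists) == 15
    low = sum(d <= 0.3 for d in dists)
    high = sum(d >= 0.7 for d in dists)
    assert low == 6 and high == 9 and low + high == 15  # nothing in between
    mid_bins = counts[(edges[:-1] >= 0.3) & (edges[:-1] < 0.7)]
    assert mid_bins.sum() == 0


def test_histogram_mass_accounts_for_excluded_pairs():
    seqs = ["AAAA", "TTTT", "----"]
    edges, counts, excl = mismatch_distribution(seqs)
    assert counts.sum() + excl == 3
    assert excl == 2


# --- sliding-window MAF ------------------------------------------------------


def _series(mafs):
    states = []
    n = 10
    for m in mafs:
        k = round(m * n)
        states.append([1] * k + [0] * (n - k))
    return MarkerSeries([f"m{i}" for i in range(len(mafs))],
                        np.array(states).T)


def test_flat_profile_at_constant_maf():
    series = _series([0.3] * 20)
    prof = sliding_window_maf(series, window=15)
    assert prof.size == 6
    assert np.allclose(prof, 0.3)


def test_window_count_arithmetic():
    prof = sliding_window_maf(_series([0.1, 0.2] * 10), window=15, step=1)
    assert prof.size == 20 - 15 + 1


def test_too_few_markers_rejected():
    with pytest.raises(ValueError):
        sliding_window_maf(_series([0.1] * 5), window=15)


def test_percentile_rank_arithmetic():
    ref = np.linspace(0.2, 0.5, 50)
    assert percentile_of_interval(0.1, ref) < 100 / 50
    assert percentile_of_interval(0.6, ref) == 100.0
    assert percentile_of_interval(ref[24], ref) == pytest.approx(50.0)


# --- Hamming networks --------------------------------------------------------


def _brute_force_mst_weight(sequences):
    labels = sorted(sequences)
    n = len(labels)
    edges = [(i, j, hamming_distance(sequences[labels[i]], sequences[labels[j]]))
             for i in range(n) for j in range(i + 1, n)]
    best = math.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x] = parent[parent[x]]
            return x

        ok = True
        for i, j, _ in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in combo))
    return best


def test_two_haplotypes_single_edge():
    net = hamming_network({"a": "AAAA", "b": "AATT"})
    assert net.primary_edges == [(0, 1, 2)]
    assert net.alternative_edges == []


def test_three_haplotype_chain():
    net = hamming_network({"h1": "AAA", "h2": "AAT", "h3": "ATT"})
    weights = sorted(w for _, _, w in net.primary_edges)
    assert weights == [1, 1]
    assert sum(w for _, _, w in net.primary_edges) == \
        _brute_force_mst_weight({"h1": "AAA", "h2": "AAT", "h3": "ATT"})


def test_mst_weight_matches_exhaustive_enumeration(rng):
    for trial in range(5):
        seqs = {f"h{i}": "".join(rng.choice(list("ACGT-"), size=8))
                for i in range(6)}
        if len(set(seqs.values())) < 6:
            continue
        net = hamming_network(seqs)
        assert sum(w for _, _, w in net.primary_edges) == \
            _brute_force_mst_weight(seqs)


def test_gap_counts_as_mutational_step():
    assert hamming_distance("A-", "AA") == 1
    assert hamming_distance("A-", "A-") == 0


def test_alternative_links_have_displaced_weight():
    # square: four haplotypes, two equally parsimonious connections
    net = hamming_network({"a": "AA", "b": "AT", "c": "TA", "d": "TT"})
    assert len(net.primary_edges) == 3
    for i, j, w in net.alternative_edges:
        # the alternative weight equals the max tree-edge weight on the path
        assert w == 1


# --- Templeton node probability ---------------------------------------------


def _oracle_templeton(j, m):
    # independent log-gamma route: m! / ((m-j)! m^j)
    return math.exp(math.lgamma(m + 1) - math.lgamma(m - j + 1) - j * math.log(m))


def test_zero_steps_certain():
    assert templeton_node_probability(0, 500) == 1.0


def test_monotone_non_increasing_in_steps():
    for m in (50, 200, 1000):
        probs = [templeton_node_probability(j, m) for j in range(0, 20)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


@pytest.mark.parametrize("j,m", [(1, 100), (5, 600), (11, 600), (3, 50), (20, 1000)])
def test_matches_independent_implementation(j, m):
    assert templeton_node_probability(j, m) == pytest.approx(_oracle_templeton(j, m))


def test_steps_beyond_length_rejected():
    with pytest.raises(ValueError):
        templeton_node_probability(5, 4)


# --- cumulative curves -------------------------------------------------------


def test_cumulative_curve_properties():
    assert cumulative_haplotype_curve([1.0]).tolist() == [1.0]
    curve = cumulative_haplotype_curve([0.25] * 4)
    assert np.allclose(curve, [0.25, 0.5, 0.75, 1.0])


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=20))
def test_cumulative_curve_monotone_ends_at_one(freqs):
    curve = cumulative_haplotype_curve(freqs)
    assert np.all(np.diff(curve) >= -1e-12)
    assert curve[-1] == pytest.approx(1.0)
    assert np.all(np.diff(np.concatenate([[0], curve])) ==
                  pytest.approx(sorted(np.array(freqs) / np.sum(freqs),
                                       reverse=True)))
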