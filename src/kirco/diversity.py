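"""Haplotype-structure diagnostics.

Heterozygosity estimators, mismatch distributions on gapped concatenated
haplotype sequences (p-distance with pairwise deletion), sliding-window
mean-MAF profiles with empirical percentile ranking, Hamming haplotype
networks (minimum spanning tree plus alternative links) with statistical-
parsimony node probabilities, and cumulative haplotype-frequency curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .selection import FrequencySpectrum

__all__ = [
    "nei_heterozygosity",
    "he_ssf",
    "mismatch_distribution",
    "sliding_window_maf",
    "percentile_of_interval",
    "hamming_network",
    "templeton_node_probability",
    "cumulative_haplotype_curve",
    "MarkerSeries",
    "NetworkGraph",
]


def nei_heterozygosity(spectrum: FrequencySpectrum) -> float:
    """Nei's unbiased heterozygosity H = n/(n-1) * (1 - Σ p_i²)."""
    n = spectrum.n
    if n < 2:
        raise ValueError("need n >= 2 for the unbiased estimator")
    return n / (n - 1.0) * (1.0 - spectrum.F)


def he_ssf(frequencies: np.ndarray) -> float:
    """Heterozygosity as one minus the sum of squared frequencies."""
    f = np.asarray(frequencies, dtype=float)
    if not math.isclose(f.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("frequencies must sum to 1")
    return float(1.0 - np.sum(f * f))


# ---------------------------------------------------------------------------
# Mismatch distributions


def pairwise_p_distance(a: str, b: str) -> float | None:
    """p-distance with pairwise deletion; None when no comparable sites."""
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    ok = (arr_a != b"-") & (arr_b != b"-")
    ncomp = int(ok.sum())
    if ncomp == 0:
        return None
    return float(np.sum(arr_a[ok] != arr_b[ok])) / ncomp


def mismatch_distribution(sequences: list[str], bin_width: float = 0.01,
                          ) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of pairwise p-distances among haplotype sequences.

    Sites with a gap in either member of a pair are excluded (pairwise
    deletion); pairs with no comparable site are excluded from the histogram.
    Returns (bin_edges, counts, n_excluded_pairs).
    """
    if len(sequences) < 2:
        raise ValueError("need at least two haplotypes")
    dists = []
    excluded = 0
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            d = pairwise_p_distance(sequences[i], sequences[j])
            if d is None:
                excluded += 1
            else:
                dists.append(d)
    dists = np.array(dists)
    nbins = max(1, int(math.ceil((dists.max() if dists.size else bin_width) / bin_width)))
    edges = np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(dists, bins=edges)
    return edges, counts, excluded


# ---------------------------------------------------------------------------
# Sliding-window MAF


@dataclass
class MarkerSeries:
    """Ordered markers with per-haplotype states; gene-presence pseudo-markers
    enter as biallelic presence/absence states."""

    marker_ids: list[str]
    states: np.ndarray  # (n_haplotypes, n_markers) of small ints

    @property
    def maf(self) -> np.ndarray:
        out = np.empty(self.states.shape[1])
        for m in range(self.states.shape[1]):
            col = self.states[:, m]
            _, cnt = np.unique(col, return_counts=True)
            freqs = cnt / col.size
            out[m] = 0.0 if freqs.size == 1 else 1.0 - freqs.max()
        return out


def marker_series_from_haplotypes(registry, locus, haplotypes: list[tuple[str, ...]],
                                  counts: list[int] | None = None) -> MarkerSeries:
    """Marker series over a haplotype set: per gene, one presence/absence
    pseudo-marker followed by the gene's polymorphic aligned-cds sites.
    ``counts`` replicates haplotypes (census weights)."""
    from .io import ABSENT

    counts = counts or [1] * len(haplotypes)
    expanded = [h for h, c in zip(haplotypes, counts) for _ in range(c)]
    ids: list[str] = []
    cols: list[np.ndarray] = []
    for gi, gene in enumerate(locus.gene_names):
        alleles = [h[gi] for h in expanded]
        presence = np.array([a != ABSENT for a in alleles], dtype=int)
        ids.append(f"{gene}:presence")
        cols.append(presence)
        seqs = np.array([list(registry.get(gene, a).cds) for a in alleles])
        for site in range(seqs.shape[1]):
            col = seqs[:, site]
            uniq = np.unique(col)
            if uniq.size > 1:
                ids.append(f"{gene}:site{site + 1}")
                lut = {s: i for i, s in enumerate(uniq)}
                cols.append(np.array([lut[s] for s in col], dtype=int))
    return MarkerSeries(ids, np.column_stack(cols))


def sliding_window_maf(series: MarkerSeries, window: int = 15, step: int = 1,
                       ) -> np.ndarray:
    """Mean per-marker MAF over fully contained sliding windows."""
    maf = series.maf
    m = maf.size
    if m < window:
        raise ValueError(f"need at least {window} markers, got {m}")
    starts = range(0, m - window + 1, step)
    return np.array([maf[s:s + window].mean() for s in starts])


def percentile_of_interval(segment_mean: float, reference: np.ndarray) -> float:
    """Empirical percentile (0-100) of a window-mean within a reference
    distribution of window means."""
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    return 100.0 * float(np.sum(ref <= segment_mean)) / ref.size


# ---------------------------------------------------------------------------
# Hamming haplotype networks


@dataclass
class NetworkGraph:
    labels: list[str]
    frequencies: list[float]
    node_probability: list[float]
    primary_edges: list[tuple[int, int, int]] = field(default_factory=list)
    alternative_edges: list[tuple[int, int, int]] = field(default_factory=list)
    # edges are (i, j, hamming steps)

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"label": l, "frequency": float(f), "probability": float(p)}
                for l, f, p in zip(self.labels, self.frequencies, self.node_probability)
            ],
            "edges": [
                {"source": int(i), "target": int(j), "steps": int(w), "primary": True}
                for i, j, w in self.primary_edges
            ] + [
                {"source": int(i), "target": int(j), "steps": int(w), "primary": False}
                for i, j, w in self.alternative_edges
            ],
        }


def hamming_distance(a: str, b: str) -> int:
    """Hamming steps on a gapped concatenation: gap-vs-base counts as a
    difference (gene absence is a mutational step), gap-vs-gap as a match."""
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    return int(np.sum(arr_a != arr_b))


def hamming_network(sequences: dict[str, str],
                    frequencies: dict[str, float] | None = None) -> NetworkGraph:
    """Haplotype network: MST primary edges (Kruskal, deterministic label-order
    tie-break) plus alternative links.

    A non-tree pair qualifies as an alternative link when its distance equals
    the maximum tree-edge weight on the tree path between the two nodes (a
    displaced, equally parsimonious connection).
    """
    labels = sorted(sequences)
    if len(labels) < 2:
        raise ValueError("need at least two distinct haplotypes")
    n = len(labels)
    m = len(next(iter(sequences.values())))
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hamming_distance(sequences[labels[i]], sequences[labels[j]])

    edges = sorted(
        ((dist[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int, int]] = []
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j, w))
            adj[i].append((j, w))
            adj[j].append((i, w))

    def max_path_weight(a: int, b: int) -> int:
        # DFS on the tree (small n)
        stack = [(a, -1, 0)]
        while stack:
            node, par, mx = stack.pop()
            if node == b:
                return mx
            for nxt, w in adj[node]:
                if nxt != par:
                    stack.append((nxt, node, max(mx, w)))
        raise RuntimeError("disconnected tree")

    tree_pairs = {(min(i, j), max(i, j)) for i, j, _ in tree}
    alt = []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in tree_pairs:
                continue
            if dist[i, j] == max_path_weight(i, j):
                alt.append((i, j, int(dist[i, j])))

    freqs = [frequencies.get(l, 0.0) if frequencies else 0.0 for l in labels]
    # node probability of each haplotype's closest connection
    probs = []
    for i in range(n):
        j_steps = min(w for a, b, w in tree if i in (a, b))
        probs.append(templeton_node_probability(j_steps, m))
    return NetworkGraph(labels, freqs, probs, tree, alt)


def templeton_node_probability(steps: int, length: int) -> float:
    """Statistical-parsimony connection probability for two haplotypes that
    differ at ``steps`` of ``length`` sites.

    Operationalised as the probability that ``steps`` substitutions placed
    uniformly over the sites hit distinct sites — i.e. that the observed
    differences equal the true number of changes, so the parsimonious
    connection holds: P = Π_{i=0}^{j-1} (1 - i/m).  P(0) = 1 and P is
    monotone non-increasing in j.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps > length:
        raise ValueError("steps cannot exceed sequence length")
    p = 1.0
    for i in range(steps):
        p *= 1.0 - i / length
    return p


# ---------------------------------------------------------------------------
# Cumulative haplotype curves


def cumulative_haplotype_curve(frequencies: np.ndarray | list[float]) -> np.ndarray:
    """Cumulative frequency series with haplotypes added in order of
    decreasing frequency; monotone non-decreasing, terminating at 1.0."""
    f = np.sort(np.asarray(frequencies, dtype=float))[::-1]
    if f.size == 0:
        raise ValueError("empty census")
    f = f / f.sum()
    return np.cumsum(f)
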