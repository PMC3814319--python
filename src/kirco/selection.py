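"""Frequency-spectrum selection statistics.

Implements Tajima's D from a gapped haplotype alignment, a Hudson-style
piecewise-constant-size coalescent simulator (infinite-sites) used to obtain
empirical two-tail significance under demographic models, the Ewens-Watterson
expected-homozygosity statistic F with Slatkin's exact test conditional on the
observed allele count, its normalized deviate F_nd, and projection of
allotypes onto binding-motif residue subsets.

Sign conventions: D > 0 and F_nd < 0 both indicate an allele-frequency
spectrum more even than the neutral expectation (balancing selection);
D < 0 / F_nd > 0 indicate skew toward one dominant allele (directional
selection or expansion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FrequencySpectrum",
    "TajimaResult",
    "EWResult",
    "DemographicModel",
    "tajimas_d",
    "tajima_constants",
    "coalescent_simulate",
    "tajima_significance",
    "ewens_watterson_f",
    "slatkin_fnd",
    "motif_project",
    "ewens_theta_for_k",
    "sample_ewens_configurations",
]


# ---------------------------------------------------------------------------
# Frequency spectra


@dataclass
class FrequencySpectrum:
    """Allele (or motif-class) counts with homozygosity summaries."""

    label: str
    variants: tuple[str, ...]
    counts: np.ndarray  # same order as variants

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size < 1 or np.any(self.counts <= 0):
            raise ValueError("spectrum needs at least one variant with positive count")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def k(self) -> int:
        return int(self.counts.size)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def F(self) -> float:
        """Expected homozygosity Σ p_i²."""
        p = self.frequencies
        return float(np.sum(p * p))

    @property
    def H_e(self) -> float:
        return 1.0 - self.F

    @property
    def monomorphic(self) -> bool:
        return self.k == 1

    @classmethod
    def from_counts(cls, counts: dict[str, float], label: str = "") -> "FrequencySpectrum":
        items = sorted(counts.items())
        return cls(label, tuple(k for k, _ in items), np.array([v for _, v in items], float))


def ewens_watterson_f(spectrum: FrequencySpectrum) -> float:
    """Watterson's homozygosity statistic F = Σ (count_i / n)²."""
    return spectrum.F


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaResult:
    S: int
    pi: float
    D: float  # nan when undefined (S == 0)
    n: int
    p_two_tail: float | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.D)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1, a2, b1, b2, c1, c2, e1, e2 constants in n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_d_from_s_pi(S: int, pi: float, n: int) -> float:
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi - S / c["a1"]) / math.sqrt(var)


def tajimas_d(sequences: list[str]) -> TajimaResult:
    """Tajima's D from a gapped alignment of haplotype sequences.

    Sites containing a gap in any sequence are excluded from the segregating
    site count S; the mean pairwise difference pi is computed with pairwise
    deletion (a site is compared for a pair when neither member has a gap).
    """
    n = len(sequences)
    if n < 4:
        raise ValueError("need at least 4 sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must be aligned to equal length")
    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(n, L)
    gap = arr == b"-"
    # S over gap-free sites only
    gapfree = ~gap.any(axis=0)
    sub = arr[:, gapfree]
    S = int(np.sum((sub != sub[0]).any(axis=0)))
    # pi with pairwise deletion
    total = 0.0
    for i in range(n):
        di = (arr[i + 1:] != arr[i]) & ~gap[i + 1:] & ~gap[i]
        total += float(di.sum())
    npairs = n * (n - 1) / 2
    pi = total / npairs
    return TajimaResult(S=S, pi=pi, D=_tajima_d_from_s_pi(S, pi, n), n=n)


# ---------------------------------------------------------------------------
# Coalescent simulation under piecewise-constant demography


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant relative population sizes looking back in time.

    ``epochs`` is a list of (start_time, relative_size) with start times
    strictly increasing from 0; times are in units of 2N0 generations.
    """

    label: str
    epochs: tuple[tuple[float, float], ...]
    theta: float

    def __post_init__(self) -> None:
        times = [t for t, _ in self.epochs]
        if not times or times[0] != 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("epoch times must strictly increase from 0")
        if any(s <= 0 for _, s in self.epochs):
            raise ValueError("epoch sizes must be positive")

    @classmethod
    def constant(cls, theta: float, label: str = "constant") -> "DemographicModel":
        return cls(label, ((0.0, 1.0),), theta)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(d["label"], tuple((float(t), float(s)) for t, s in d["epochs"]),
                   float(d["theta"]))


def _coalescence_times(rng: np.random.Generator, n: int,
                       epochs: tuple[tuple[float, float], ...]) -> list[float]:
    """Waiting times between successive coalescences for k = n ... 2."""
    times = []
    t = 0.0
    starts = [e[0] for e in epochs]
    sizes = [e[1] for e in epochs]
    k = n
    while k > 1:
        rate_unit = k * (k - 1) / 2.0
        # exponential with piecewise rate rate_unit / size(t)
        target = rng.exponential()
        t0 = t
        while True:
            ei = np.searchsorted(starts, t0, side="right") - 1
            end = starts[ei + 1] if ei + 1 < len(starts) else math.inf
            rate = rate_unit / sizes[ei]
            span = end - t0
            if rate * span >= target:
                t0 += target / rate
                break
            target -= rate * span
            t0 = end
        times.append(t0 - t)
        t = t0
        k -= 1
    return times


def _genealogy(rng: np.random.Generator, n: int,
               epochs: tuple[tuple[float, float], ...],
               track_leaves: bool = False):
    """Simulate one genealogy; return a list of (descendant_count_or_leafset,
    branch_duration) intervals over which mutations can fall."""
    waits = _coalescence_times(rng, n, epochs)
    if track_leaves:
        lineages: list[set[int]] = [{i} for i in range(n)]
    else:
        lineages = [1] * n  # descendant counts
    intervals: list[tuple[object, float]] = []
    for w, k in zip(waits, range(n, 1, -1)):
        for lin in lineages:
            intervals.append((lin, w))
        # each active lineage exists for w, then a random pair merges
        i, j = sorted(rng.choice(k, size=2, replace=False))
        if track_leaves:
            merged = lineages[i] | lineages[j]
        else:
            merged = lineages[i] + lineages[j]
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    # collapse interval durations but keep lineage identity per interval entry
    return intervals


def _throw_mutations(rng: np.random.Generator, intervals, theta: float) -> list:
    durations = np.array([d for _, d in intervals])
    total = durations.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return []
    probs = durations / total
    which = rng.choice(len(intervals), size=n_mut, p=probs)
    return [intervals[w][0] for w in which]


def coalescent_simulate(model: DemographicModel, n: int, reps: int,
                        seed: int | np.random.Generator) -> list[TajimaResult]:
    """Simulate ``reps`` neutral infinite-sites replicates of sample size n
    under the model; returns per-replicate S, pi and D."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    npairs = n * (n - 1) / 2
    out = []
    for _ in range(reps):
        intervals = _genealogy(rng, n, model.epochs)
        muts = _throw_mutations(rng, intervals, model.theta)
        S = len(muts)
        pi = sum(c * (n - c) for c in muts) / npairs
        D = _tajima_d_from_s_pi(S, pi, n) if n >= 4 else float("nan")
        out.append(TajimaResult(S=S, pi=pi, D=D, n=n))
    return out


def coalescent_sample_spectrum(model: DemographicModel, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """One neutral replicate's haplotype-class counts (infinite sites):
    leaves sharing an identical mutation set form one class."""
    intervals = _genealogy(rng, n, model.epochs, track_leaves=True)
    muts = _throw_mutations(rng, intervals, model.theta)
    key = [frozenset() for _ in range(n)]
    sets = [set() for _ in range(n)]
    for m, leafset in enumerate(muts):
        for leaf in leafset:
            sets[leaf].add(m)
    classes: dict[frozenset, int] = {}
    for s in sets:
        fs = frozenset(s)
        classes[fs] = classes.get(fs, 0) + 1
    return np.array(sorted(classes.values(), reverse=True), dtype=int)


def tajima_significance(observed: TajimaResult | float,
                        sims: list[TajimaResult]) -> float:
    """Empirical two-tail p of an observed D against simulated replicates.

    Replicates with undefined D (S = 0) are dropped.  p uses rank tails with
    an add-one correction: p = 2 * min(tails) / (reps + 1), capped at 1.
    """
    d_obs = observed.D if isinstance(observed, TajimaResult) else float(observed)
    ds = np.array([r.D for r in sims if r.defined])
    if ds.size == 0:
        raise ValueError("no defined-D replicates")
    lo = int(np.sum(ds <= d_obs)) + 1
    hi = int(np.sum(ds >= d_obs)) + 1
    return min(1.0, 2.0 * min(lo, hi) / (ds.size + 1))


# ---------------------------------------------------------------------------
# Ewens-Watterson / Slatkin exact test


@dataclass
class EWResult:
    F_obs: float
    k: int
    n: int
    p_slatkin: float
    F_nd: float
    n_sim: int
    monomorphic: bool = False


def ewens_theta_for_k(n: int, k: int) -> float:
    """Solve E[K | theta, n] = sum_i theta/(theta+i) = k for theta."""
    i = np.arange(n, dtype=float)

    def ek(theta: float) -> float:
        return float(np.sum(theta / (theta + i)))

    if k <= 1:
        return 1e-6
    if k >= n:
        return 1e6
    return brentq(lambda th: ek(th) - k, 1e-9, 1e7)


def sample_ewens_configurations(n: int, theta: float, n_runs: int,
                                rng: np.random.Generator,
                                k_max: int | None = None) -> np.ndarray:
    """Vectorised Chinese-restaurant sampling of Ewens allele configurations.

    Returns an (n_runs, k_max) count matrix; rows whose allele count exceeded
    k_max are all-zero (caller must discard them).
    """
    if k_max is None:
        k_max = n
    counts = np.zeros((n_runs, k_max), dtype=np.int64)
    counts[:, 0] = 1
    ntab = np.ones(n_runs, dtype=np.int64)
    overflow = np.zeros(n_runs, dtype=bool)
    for i in range(1, n):
        u = rng.random(n_runs) * (theta + i)
        new = u < theta
        ok_new = new & (ntab < k_max)
        overflow |= new & (ntab >= k_max)
        rows = np.nonzero(ok_new)[0]
        counts[rows, ntab[rows]] = 1
        ntab[rows] += 1
        old_rows = np.nonzero(~new)[0]
        if old_rows.size:
            r = (u[old_rows] - theta)  # uniform in (0, i) = (0, total occupancy)
            c = np.cumsum(counts[old_rows], axis=1)
            idx = (c <= r[:, None]).sum(axis=1)
            counts[old_rows, idx] += 1
    counts[overflow] = 0
    return counts


def slatkin_fnd(spectrum: FrequencySpectrum, n_sim: int = 10000,
                seed: int | np.random.Generator = 0) -> EWResult:
    """Slatkin's exact test of the Ewens-Watterson homozygosity and its
    normalized deviate.

    The neutral null conditions on the observed allele count k and sample
    size n: configurations are drawn from the Ewens sampling formula (which,
    conditional on k, does not depend on theta) by Chinese-restaurant
    construction with theta solved so E[k] matches, then rejection on k.
    p = Pr(F_sim <= F_obs) with add-one correction; F_nd = (F_obs - mean F_sim)
    / sd F_sim.
    """
    n = int(round(spectrum.n))
    k = spectrum.k
    F_obs = spectrum.F
    if k < 2:
        return EWResult(F_obs, k, n, 1.0, float("nan"), 0, monomorphic=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = ewens_theta_for_k(n, k)
    k_max = min(n, max(2 * k + 10, 20))
    fs: list[np.ndarray] = []
    accepted = 0
    attempts = 0
    batch = max(n_sim, 1000)
    while accepted < n_sim:
        cfg = sample_ewens_configurations(n, theta, batch, rng, k_max=k_max)
        ks = (cfg > 0).sum(axis=1)
        keep = cfg[ks == k]
        attempts += batch
        if keep.size:
            p = keep / n
            fs.append(np.sum(p * p, axis=1))
            accepted += keep.shape[0]
        if attempts > 1e4 and accepted / attempts < 1e-4:
            raise RuntimeError(
                "rejection acceptance rate below 1e-4; use direct enumeration "
                f"for n={n}, k={k}"
            )
    f_sim = np.concatenate(fs)[:n_sim]
    p_slatkin = (1 + int(np.sum(f_sim <= F_obs))) / (1 + n_sim)
    sd = float(f_sim.std(ddof=1))
    fnd = (F_obs - float(f_sim.mean())) / sd if sd > 0 else 0.0
    return EWResult(F_obs, k, n, p_slatkin, fnd, n_sim)


# ---------------------------------------------------------------------------
# Motif projection


def motif_project(allotype_freqs: list[tuple["object", float]],
                  residues: list[int], label: str = "") -> FrequencySpectrum:
    """Collapse allotypes by identity of their residue-subset substring.

    ``allotype_freqs`` pairs AlleleRecord-like objects (with ``.protein`` and
    ``.residue``) with frequencies or counts; returns the projected spectrum.
    Monomorphic projections are representable (k = 1, ``monomorphic`` True).
    """
    classes: dict[str, float] = {}
    for rec, w in allotype_freqs:
        prot = rec.protein
        for r in residues:
            if r < 1 or r > len(prot):
                raise ValueError(
                    f"residue {r} outside protein length {len(prot)} of {rec.name}"
                )
        key = "".join(prot[r - 1] for r in residues)
        classes[key] = classes.get(key, 0.0) + float(w)
    return FrequencySpectrum.from_counts(classes, label=label)
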