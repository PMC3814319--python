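#!/usr/bin/env python
"""Haplotype-structure diagnostics per locus segment: mismatch distributions
(p-distance, pairwise deletion), cumulative haplotype-frequency curves at
allele and allotype resolution, sliding-window mean-MAF profiles, and the
Hamming haplotype network of the centromeric and telomeric KIR segments.

Writes results/mismatch_<segment>.tsv, results/cumulative_<locus>.tsv,
results/maf_profile_KIR.tsv and results/network_<segment>.json.
"""

import json
from pathlib import Path

from kirco.diversity import (cumulative_haplotype_curve, hamming_network,
                             marker_series_from_haplotypes,
                             mismatch_distribution, sliding_window_maf)
from kirco.io import haplotype_sequence
from kirco.phasing import haplotype_census, phase_cohort
from kirco.simulate import default_sim_config, simulate_cohort

SEED = 20131031 % (2**31 - 1)
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = default_sim_config(SEED, n_pairs=104, n_unrelated=27)
    cohort, _ = simulate_cohort(cfg)
    (ROOT / "results").mkdir(exist_ok=True)
    kir = cohort.locus_models["KIR"]
    b = kir.cen_tel_boundary
    phased = phase_cohort(cohort, "KIR")
    census = haplotype_census(phased)

    for segment, sl in (("KIR_cen", slice(0, b)), ("KIR_tel", slice(b, None))):
        seg_counts: dict[str, float] = {}
        seg_seq: dict[str, str] = {}
        for hap, c in census.counts.items():
            key = ",".join(hap[sl])
            seg_counts[key] = seg_counts.get(key, 0.0) + c
            seg_seq[key] = haplotype_sequence(cohort.registry, kir, hap, sl)
        seqs = [s for k, s in seg_seq.items() for _ in range(int(seg_counts[k]))]
        edges, counts, _ = mismatch_distribution(seqs, bin_width=0.005)
        with open(ROOT / "results" / f"mismatch_{segment}.tsv", "w") as fh:
            fh.write("bin_left\tbin_right\tcount\n")
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                fh.write(f"{lo:.4f}\t{hi:.4f}\t{c}\n")
        freqs = {k: v / census.two_n for k, v in seg_counts.items()}
        net = hamming_network(seg_seq, freqs)
        (ROOT / "results" / f"network_{segment}.json").write_text(
            json.dumps(net.to_dict(), indent=1) + "\n")
        print(f"{segment}: {len(seg_seq)} distinct segment haplotypes, "
              f"{len(net.primary_edges)} tree edges, "
              f"{len(net.alternative_edges)} alternative links, "
              f"min node probability "
              f"{min(net.node_probability):.3f}")

    series = marker_series_from_haplotypes(
        cohort.registry, kir, list(census.counts),
        [int(c) for c in census.counts.values()])
    profile = sliding_window_maf(series, window=15, step=1)
    with open(ROOT / "results" / "maf_profile_KIR.tsv", "w") as fh:
        fh.write("window_start_marker\tmean_maf\n")
        fh.writelines(f"{series.marker_ids[i]}\t{v:.5f}\n"
                      for i, v in enumerate(profile))
    print(f"MAF profile: {profile.size} windows over "
          f"{len(series.marker_ids)} markers")

    for locus_id in ("KIR", "HLA"):
        locus = cohort.locus_models[locus_id]
        ph = phase_cohort(cohort, locus_id)
        cen = haplotype_census(ph)
        allo = cen.allotype_level(cohort.registry, locus)
        c_allele = cumulative_haplotype_curve(list(cen.frequencies.values()))
        c_allo = cumulative_haplotype_curve(list(allo.frequencies.values()))
        with open(ROOT / "results" / f"cumulative_{locus_id}.tsv", "w") as fh:
            fh.write("rank\tcumulative_allele\tcumulative_allotype\n")
            for i in range(max(c_allele.size, c_allo.size)):
                a = f"{c_allele[i]:.5f}" if i < c_allele.size else ""
                al = f"{c_allo[i]:.5f}" if i < c_allo.size else ""
                fh.write(f"{i + 1}\t{a}\t{al}\n")
        print(f"{locus_id}: k={cen.k} allele-level / {allo.k} allotype-level "
              f"haplotypes")


if __name__ == "__main__":
    main()
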