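"""End-to-end pipeline: simulate -> phase -> ligands -> selection ->
diversity -> coevolve, seed-deterministic with a consolidated report.

A single global seed fans out to per-stage substreams derived by stable
hashing of the stage name, so re-running one stage in isolation reproduces
its outputs.  Every run writes a JSON manifest (seeds, stage parameters,
input hashes) next to the stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .coevolution import coevolution_scan
from .diversity import (cumulative_haplotype_curve, hamming_network,
                        marker_series_from_haplotypes, mismatch_distribution,
                        nei_heterozygosity, sliding_window_maf)
from .io import ABSENT, Cohort, haplotype_sequence
from .ligands import (cohort_pair_distribution, load_default_binding_sites,
                      load_default_epitope_config, load_default_interaction_table)
from .nomenclature import allotype_name
from .phasing import HaplotypeCensus, haplotype_census, phase_cohort
from .selection import (DemographicModel, FrequencySpectrum, coalescent_simulate,
                        motif_project, slatkin_fnd, tajima_significance, tajimas_d)
from .simulate import default_sim_config, simulate_cohort, write_outputs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (crc32 of the stage name folded into
    the global seed; kept below 2**31)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "phase", "ligands", "selection",
                               "diversity", "coevolve")
    simulate_params: dict = field(default_factory=dict)
    selection_params: dict = field(default_factory=lambda: {
        "model": "constant", "theta": 5.0, "reps": 1000})
    coevolve_params: dict = field(default_factory=lambda: {
        "alpha": 0.05, "n_perm": 499})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _allotype_spectrum(census: HaplotypeCensus, cohort: Cohort, locus_id: str,
                       gene: str) -> FrequencySpectrum | None:
    locus = cohort.locus_models[locus_id]
    gi = locus.gene_names.index(gene)
    counts: dict[str, float] = {}
    for hap, c in census.counts.items():
        a = hap[gi]
        if a == ABSENT:
            continue
        counts[allotype_name(a)] = counts.get(allotype_name(a), 0.0) + c
    if not counts:
        return None
    return FrequencySpectrum.from_counts(counts, label=gene)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order; halts on the first failing stage
    (partial outputs are preserved) and returns the consolidated report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": cfg.to_dict(), "stage_seeds": {},
                      "input_hashes": {}}
    state: dict = {}
    for stage in cfg.stages:
        sseed = stage_seed(cfg.seed, stage)
        manifest["stage_seeds"][stage] = sseed
        logger.info("stage=%s seed=%d", stage, sseed)
        try:
            _STAGES[stage](cfg, sseed, out, state, report)
        except Exception:
            logger.error("stage %s failed; partial outputs preserved in %s",
                         stage, out)
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise
    for name in ("genotypes.tsv", "alleles.fasta"):
        p = out / "cohort" / name
        if p.exists():
            manifest["input_hashes"][name] = _file_hash(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _stage_simulate(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                    report: dict) -> None:
    sim_cfg = default_sim_config(seed, **cfg.simulate_params)
    cohort, truth = simulate_cohort(sim_cfg)
    write_outputs(cohort, truth, sim_cfg, out / "cohort")
    state["cohort"] = cohort
    state["truth"] = truth
    report["stages"]["simulate"] = cohort.summary()


def _require(state: dict, key: str, needed_by: str):
    if key not in state:
        raise RuntimeError(f"stage {needed_by!r} requires {key!r}; enable the "
                           "producing stage or provide inputs")
    return state[key]


def _stage_phase(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                 report: dict) -> None:
    cohort: Cohort = _require(state, "cohort", "phase")
    phased = {}
    censuses = {}
    rows = []
    census_rows = []
    for locus_id, locus in cohort.locus_models.items():
        ph = phase_cohort(cohort, locus_id)
        phased[locus_id] = ph
        for pi in ph.values():
            for idx, hap in enumerate(pi.haplotypes):
                rows.append((pi.id, locus_id, idx, ",".join(hap), pi.resolution))
        cen = haplotype_census(ph, include_maternal_nontransmitted=False)
        cen_all = haplotype_census(ph, include_maternal_nontransmitted=True)
        censuses[locus_id] = {"children": cen, "total": cen_all}
        for label, c in (("children", cen), ("total", cen_all)):
            for hap, n in sorted(c.counts.items(), key=lambda x: -x[1]):
                census_rows.append((locus_id, label, ",".join(hap), n))
        report["stages"].setdefault("phase", {})[locus_id] = {
            "two_n_children": cen.two_n,
            "two_n_total": cen_all.two_n,
            "k_children": cen.k,
            "k_total": cen_all.k,
        }
    with open(out / "haplotypes.tsv", "w") as fh:
        fh.write("individual_id\tlocus\thap_index\talleles\tresolution\n")
        fh.writelines("\t".join(map(str, r)) + "\n" for r in rows)
    with open(out / "census.tsv", "w") as fh:
        fh.write("locus\tset\thaplotype\tcount\n")
        fh.writelines("\t".join(map(str, r)) + "\n" for r in census_rows)
    state["phased"] = phased
    state["censuses"] = censuses


def _stage_ligands(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                   report: dict) -> None:
    cohort: Cohort = _require(state, "cohort", "ligands")
    dist = cohort_pair_distribution(cohort, load_default_epitope_config(),
                                    load_default_interaction_table())
    with open(out / "pairs.tsv", "w") as fh:
        fh.write("individual_id\treceptor\tligand\n")
        for ind, pairs in dist["pairs"].items():
            for k, h in pairs:
                fh.write(f"{ind}\t{k}\t{h}\n")
    summary = {k: dist[k] for k in ("mean", "interval95", "histogram")}
    with open(out / "pair_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    report["stages"]["ligands"] = summary


def _stage_selection(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                     report: dict) -> None:
    cohort: Cohort = _require(state, "cohort", "selection")
    censuses = _require(state, "censuses", "selection")
    params = cfg.selection_params
    model = DemographicModel(params.get("model", "constant"),
                             tuple(tuple(e) for e in params.get(
                                 "epochs", [(0.0, 1.0)])),
                             params.get("theta", 5.0))
    rng = np.random.default_rng(seed)
    sites = load_default_binding_sites()
    rows = []
    sel_report = {}
    for locus_id, cen in censuses.items():
        census: HaplotypeCensus = cen["children"]
        locus = cohort.locus_models[locus_id]
        seqs = []
        for hap, c in census.counts.items():
            seqs += [haplotype_sequence(cohort.registry, locus, hap)] * int(c)
        taj = tajimas_d(seqs)
        sims = coalescent_simulate(model, min(len(seqs), 50),
                                   int(params.get("reps", 1000)), rng)
        p2 = tajima_significance(taj, sims) if taj.defined else float("nan")
        sel_report[locus_id] = {"S": taj.S, "pi": taj.pi, "D": taj.D,
                                "p_two_tail": p2}
        rows.append((locus_id, "ALL_SITES", "-", "-", "-", "-",
                     f"{taj.D:.4f}", f"{p2:.4g}"))
        for gene in locus.gene_names:
            spec = _allotype_spectrum(census, cohort, locus_id, gene)
            if spec is None or gene not in sites.sites:
                continue
            gi = locus.gene_names.index(gene)
            freqs = {}
            for hap, c in census.counts.items():
                if hap[gi] != ABSENT:
                    freqs[allotype_name(hap[gi])] = freqs.get(allotype_name(hap[gi]), 0) + c
            recs = {allotype_name(a): cohort.registry.get(gene, a)
                    for hap, _ in census.counts.items() for a in [hap[gi]]
                    if a != ABSENT}
            pairs = [(recs[n], c) for n, c in freqs.items()]
            for motif, residues in sites.exclusive_sets(gene).items():
                residues = [r for r in residues
                            if all(r <= len(rec.protein) for rec, _ in pairs)]
                if not residues:
                    continue
                spec_m = motif_project(pairs, list(residues), label=f"{gene}:{motif}")
                if spec_m.monomorphic:
                    rows.append((locus_id, gene, motif, spec_m.k, f"{spec_m.F:.4f}",
                                 "-", "-", "-"))
                    continue
                ew = slatkin_fnd(spec_m, n_sim=int(params.get("n_sim", 2000)),
                                 seed=rng)
                rows.append((locus_id, gene, motif, ew.k, f"{ew.F_obs:.4f}",
                             f"{ew.F_nd:.3f}", f"{ew.p_slatkin:.4g}", "-"))
    with open(out / "selection.tsv", "w") as fh:
        fh.write("locus\tgene\tmotif\tk\tF\tF_nd\tp_slatkin\tp_D_two_tail\n")
        fh.writelines("\t".join(map(str, r)) + "\n" for r in rows)
    report["stages"]["selection"] = sel_report


def _stage_diversity(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                     report: dict) -> None:
    cohort: Cohort = _require(state, "cohort", "diversity")
    censuses = _require(state, "censuses", "diversity")
    div_report = {}
    for locus_id, cen in censuses.items():
        census: HaplotypeCensus = cen["children"]
        locus = cohort.locus_models[locus_id]
        seqs = {" | ".join(h): haplotype_sequence(cohort.registry, locus, h)
                for h in census.counts}
        freqs = {" | ".join(h): f for h, f in census.frequencies.items()}
        edges, counts, _ = mismatch_distribution(list(seqs.values()))
        with open(out / f"mismatch_{locus_id}.tsv", "w") as fh:
            fh.write("bin_left\tbin_right\tcount\n")
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                fh.write(f"{lo:.4f}\t{hi:.4f}\t{c}\n")
        series = marker_series_from_haplotypes(cohort.registry, locus,
                                               list(census.counts),
                                               [int(c) for c in census.counts.values()])
        window = min(15, len(series.marker_ids))
        profile = sliding_window_maf(series, window=window)
        with open(out / f"maf_profile_{locus_id}.tsv", "w") as fh:
            fh.write("window_start\tmean_maf\n")
            fh.writelines(f"{i}\t{v:.5f}\n" for i, v in enumerate(profile))
        top = dict(sorted(freqs.items(), key=lambda x: -x[1])[:30])
        net = hamming_network({k: seqs[k] for k in top}, top)
        with open(out / f"network_{locus_id}.json", "w") as fh:
            json.dump(net.to_dict(), fh, indent=1)
        curve = cumulative_haplotype_curve(list(census.frequencies.values()))
        allo = census.allotype_level(cohort.registry, locus)
        curve_allo = cumulative_haplotype_curve(list(allo.frequencies.values()))
        with open(out / f"cumulative_{locus_id}.tsv", "w") as fh:
            fh.write("rank\tcumulative_allele\tcumulative_allotype\n")
            for i in range(max(curve.size, curve_allo.size)):
                a = f"{curve[i]:.5f}" if i < curve.size else ""
                b = f"{curve_allo[i]:.5f}" if i < curve_allo.size else ""
                fh.write(f"{i + 1}\t{a}\t{b}\n")
        spec = FrequencySpectrum.from_counts(
            {" | ".join(h): c for h, c in census.counts.items()}, locus_id)
        div_report[locus_id] = {
            "H_nei": nei_heterozygosity(spec),
            "k_allele": census.k,
            "k_allotype": allo.k,
            "n_windows": int(profile.size),
        }
    report["stages"]["diversity"] = div_report


def _stage_coevolve(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                    report: dict) -> None:
    cohort: Cohort = _require(state, "cohort", "coevolve")
    phased = _require(state, "phased", "coevolve")
    if "HLA" not in phased or "KIR" not in phased:
        raise RuntimeError("coevolve requires phased HLA and KIR loci")
    params = cfg.coevolve_params
    hla_locus = cohort.locus_models["HLA"]
    kir_locus = cohort.locus_models["KIR"]
    hits = coevolution_scan(
        phased["HLA"], phased["KIR"], cohort.registry, hla_locus, kir_locus,
        list(hla_locus.gene_names), list(kir_locus.gene_names),
        alpha=params.get("alpha", 0.05), n_perm=params.get("n_perm", 499),
        seed=seed, adjust=bool(params.get("adjust", False)))
    with open(out / "scan.tsv", "w") as fh:
        fh.write("hla_gene\thla_residues\tkir_gene\tkir_residues\tz\tp\t"
                 "p_bonferroni\tr2_class\n")
        for h in hits:
            fh.write("\t".join([
                h.hla_group.gene, ",".join(map(str, h.hla_group.positions)),
                h.kir_group.gene, ",".join(map(str, h.kir_group.positions)),
                f"{h.mantel.z:.5f}", f"{h.mantel.p:.4g}",
                f"{h.p_bonferroni:.4g}", h.hla_group.ld_class + "/" +
                h.kir_group.ld_class]) + "\n")
    report["stages"]["coevolve"] = {
        "n_hits": len(hits),
        "top": None if not hits else {
            "hla": [hits[0].hla_group.gene, list(hits[0].hla_group.positions)],
            "kir": [hits[0].kir_group.gene, list(hits[0].kir_group.positions)],
            "p": hits[0].mantel.p,
        },
    }


_STAGES = {
    "simulate": _stage_simulate,
    "phase": _stage_phase,
    "ligands": _stage_ligands,
    "selection": _stage_selection,
    "diversity": _stage_diversity,
    "coevolve": _stage_coevolve,
}
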