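"""Worked examples built from small synthetic allele registries.

The sequences here are synthetic stand-ins: they carry the correct
epitope-determining residues (Bw4 77-83 motifs, HLA-C position 80) embedded
in arbitrary backbone sequence, which is all the epitope and pair-counting
rules read.
"""

from __future__ import annotations

import numpy as np

from .io import ABSENT, AlleleRecord, GeneModel, Individual, LocusModel, Registry
from .simulate import BW4_WINDOW, BW6_WINDOW, _AA, _protein_to_cds

__all__ = ["single_pair_individual"]

_LEN = 100


def _protein(rng: np.random.Generator, overrides: dict[int, str]) -> str:
    prot = list(rng.choice(list(_AA), size=_LEN))
    for pos, aa in overrides.items():
        prot[pos - 1] = aa
    return "".join(prot)


def _bw4(extra=None):
    d = {77 + i: aa for i, aa in enumerate(BW4_WINDOW)}
    d.update(extra or {})
    return d


def _bw6(extra=None):
    d = {77 + i: aa for i, aa in enumerate(BW6_WINDOW)}
    d.update(extra or {})
    return d


def single_pair_individual() -> tuple[Individual, Registry, dict[str, LocusModel]]:
    """The one-pair compound genotype: homozygous A*23:01 / B*44:03 /
    C*04:01 with KIR2DL2*001, no KIR2DL1/S1/S2, and expression-null
    KIR3DL1*004.

    Under the default epitope rules and interaction table this individual
    carries exactly one viable receptor-ligand allotype pair,
    (KIR2DL2*001, C*04:01): C*04:01 is C2-bearing yet accepted by KIR2DL2
    through the cross-reactivity exception, B*44:03 carries Bw4 but its
    receptor KIR3DL1*004 is not expressed, and A*23:01 offers no A3/11
    epitope to KIR3DL2.
    """
    rng = np.random.default_rng(230144)  # fixed backbone; residues set below
    hla_genes = tuple(GeneModel(g, True, _LEN * 3) for g in ("HLA-A", "HLA-B", "HLA-C"))
    kir_names = ["KIR3DL3", "KIR2DL2/3", "KIR2DL1", "KIR2DL4", "KIR3DL1/S1", "KIR3DL2"]
    kir_genes = tuple(GeneModel(g, g in ("KIR3DL3", "KIR2DL4", "KIR3DL2"), _LEN * 3)
                      for g in kir_names)
    models = {"HLA": LocusModel("HLA", hla_genes, 0),
              "KIR": LocusModel("KIR", kir_genes, 3)}
    records = [
        AlleleRecord("HLA-A", "A*23:01", _protein_to_cds(_protein(rng, _bw4()))),
        AlleleRecord("HLA-B", "B*44:03", _protein_to_cds(_protein(rng, _bw4({77: "D", 80: "T"})))),
        AlleleRecord("HLA-B", "B*35:01", _protein_to_cds(_protein(rng, _bw6()))),
        AlleleRecord("HLA-B", "B*53:01", _protein_to_cds(_protein(rng, _bw4()))),
        AlleleRecord("HLA-C", "C*04:01", _protein_to_cds(_protein(rng, {80: "K"}))),
        AlleleRecord("KIR3DL3", "KIR3DL3*001", _protein_to_cds(_protein(rng, {}))),
        AlleleRecord("KIR2DL2/3", "KIR2DL2*001", _protein_to_cds(_protein(rng, {}))),
        AlleleRecord("KIR2DL4", "KIR2DL4*001", _protein_to_cds(_protein(rng, {}))),
        AlleleRecord("KIR3DL1/S1", "KIR3DL1*004", _protein_to_cds(_protein(rng, {})),
                     expressed=False),
        AlleleRecord("KIR3DL1/S1", "KIR3DL1*001", _protein_to_cds(_protein(rng, {}))),
        AlleleRecord("KIR3DL2", "KIR3DL2*001", _protein_to_cds(_protein(rng, {}))),
    ]
    registry = Registry(records, models)
    ind = Individual("fig_example", None, {
        "HLA-A": ("A*23:01", "A*23:01"),
        "HLA-B": ("B*44:03", "B*44:03"),
        "HLA-C": ("C*04:01", "C*04:01"),
        "KIR3DL3": ("KIR3DL3*001", "KIR3DL3*001"),
        "KIR2DL2/3": ("KIR2DL2*001", "KIR2DL2*001"),
        "KIR2DL1": (ABSENT, ABSENT),
        "KIR2DL4": ("KIR2DL4*001", "KIR2DL4*001"),
        "KIR3DL1/S1": ("KIR3DL1*004", "KIR3DL1*004"),
        "KIR3DL2": ("KIR3DL2*001", "KIR3DL2*001"),
    })
    return ind, registry, models
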