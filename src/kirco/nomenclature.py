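"""Parsing and formatting of KIR/HLA allele and haplotype-motif nomenclature.

KIR alleles are written ``GENE*DDDDD`` where the first three digits identify
the allotype (the unique protein) and the optional fourth and fifth digits
identify synonymous variants of it.  Haplotype gene-content motifs are written
``cA01``/``tB04`` etc.: a centromeric/telomeric region letter, an A/B group
letter and two digits naming the gene-content motif, optionally extended by
colon-separated three-digit fields for non-synonymous and synonymous allelic
differences.  HLA class I alleles use the modern colon-delimited convention
(``B*53:01``); two fields identify the allotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "NomenclatureError",
    "KirAlleleName",
    "HlaAlleleName",
    "MotifName",
    "parse_kir_allele_name",
    "parse_hla_allele_name",
    "parse_motif_name",
    "allotype_name",
]


class NomenclatureError(ValueError):
    """Raised when an allele or motif name does not parse."""


_KIR_RE = re.compile(r"^(?P<gene>KIR[23]D[LSP]\d[A-Zv]?(?:/\d[A-Zv]*)?)\*(?P<digits>\d{3}|\d{5})$")
_HLA_RE = re.compile(r"^(?P<gene>[A-C]|HLA-[A-C])\*(?P<f1>\d{2,3})(?::(?P<f2>\d{2,3}))?(?P<suffix>[NLSCAQ])?$")
_MOTIF_RE = re.compile(
    r"^(?P<region>[ct])(?P<group>[AB])(?P<content>\d{2})"
    r"(?::(?P<nonsyn>\d{3})(?::(?P<syn>\d{3}))?)?$"
)


@dataclass(frozen=True)
class KirAlleleName:
    """A parsed KIR allele name, e.g. KIR3DL1*01502."""

    gene: str
    allotype_digits: str
    synonymous_digits: str | None = None

    def __post_init__(self) -> None:
        if len(self.allotype_digits) != 3 or not self.allotype_digits.isdigit():
            raise NomenclatureError(
                f"allotype field must be 3 digits, got {self.allotype_digits!r}"
            )
        if self.synonymous_digits is not None and (
            len(self.synonymous_digits) != 2 or not self.synonymous_digits.isdigit()
        ):
            raise NomenclatureError(
                f"synonymous field must be 2 digits, got {self.synonymous_digits!r}"
            )

    def __str__(self) -> str:
        tail = self.synonymous_digits or ""
        return f"{self.gene}*{self.allotype_digits}{tail}"

    @property
    def allotype(self) -> str:
        """Name of the encoded allotype (synonymous field dropped)."""
        return f"{self.gene}*{self.allotype_digits}"


@dataclass(frozen=True)
class HlaAlleleName:
    """A parsed colon-delimited HLA class I allele name, e.g. B*53:01."""

    gene: str
    field1: str
    field2: str | None = None
    suffix: str | None = None

    def __str__(self) -> str:
        s = f"{self.gene}*{self.field1}"
        if self.field2 is not None:
            s += f":{self.field2}"
        if self.suffix is not None:
            s += self.suffix
        return s

    @property
    def allotype(self) -> str:
        if self.field2 is None:
            return f"{self.gene}*{self.field1}"
        return f"{self.gene}*{self.field1}:{self.field2}"


@dataclass(frozen=True)
class MotifName:
    """A parsed haplotype gene-content motif name, e.g. cA01 or tB04:001:002."""

    region: str  # "centromeric" | "telomeric"
    group: str  # "A" | "B"
    content_digits: str
    nonsyn_digits: str | None = None
    syn_digits: str | None = None

    def __post_init__(self) -> None:
        if self.region not in ("centromeric", "telomeric"):
            raise NomenclatureError(f"bad region {self.region!r}")
        if self.group not in ("A", "B"):
            raise NomenclatureError(f"bad group {self.group!r}")

    def __str__(self) -> str:
        s = f"{self.region[0]}{self.group}{self.content_digits.zfill(2)}"
        if self.nonsyn_digits is not None:
            s += f":{self.nonsyn_digits.zfill(3)}"
            if self.syn_digits is not None:
                s += f":{self.syn_digits.zfill(3)}"
        return s


def parse_kir_allele_name(s: str) -> KirAlleleName:
    """Parse a KIR allele name into gene, allotype and synonymous fields.

    >>> parse_kir_allele_name("KIR3DL1*01502")
    KirAlleleName(gene='KIR3DL1', allotype_digits='015', synonymous_digits='02')
    """
    m = _KIR_RE.match(s)
    if m is None:
        if "*" not in s:
            raise NomenclatureError(f"{s!r}: missing '*' separator between gene and digits")
        gene, _, digits = s.partition("*")
        if not gene.startswith("KIR"):
            raise NomenclatureError(f"{s!r}: gene field {gene!r} is not a KIR gene name")
        raise NomenclatureError(
            f"{s!r}: digit field {digits!r} must be 3 (allotype) or 5 (allele) digits"
        )
    digits = m.group("digits")
    return KirAlleleName(
        gene=m.group("gene"),
        allotype_digits=digits[:3],
        synonymous_digits=digits[3:] or None,
    )


def parse_hla_allele_name(s: str) -> HlaAlleleName:
    """Parse a colon-delimited HLA class I allele name (two fields required
    for full resolution; one-field group names such as ``A*03`` are allowed)."""
    m = _HLA_RE.match(s)
    if m is None:
        raise NomenclatureError(f"{s!r}: not a colon-delimited HLA class I allele name")
    gene = m.group("gene").removeprefix("HLA-")
    return HlaAlleleName(gene=gene, field1=m.group("f1"), field2=m.group("f2"),
                         suffix=m.group("suffix"))


def parse_motif_name(s: str) -> MotifName:
    """Parse a centromeric/telomeric haplotype motif name.

    >>> parse_motif_name("cA01")
    MotifName(region='centromeric', group='A', content_digits='01', nonsyn_digits=None, syn_digits=None)
    """
    m = _MOTIF_RE.match(s)
    if m is None:
        raise NomenclatureError(
            f"{s!r}: motif names match [ct][AB]DD(:DDD(:DDD)?)?"
        )
    return MotifName(
        region={"c": "centromeric", "t": "telomeric"}[m.group("region")],
        group=m.group("group"),
        content_digits=m.group("content"),
        nonsyn_digits=m.group("nonsyn"),
        syn_digits=m.group("syn"),
    )


def allotype_name(allele: str) -> str:
    """Collapse an allele name to its allotype name.

    KIR names drop the synonymous (4th-5th digit) field; HLA names keep the
    first two colon-delimited fields.  The reserved ``ABSENT`` state maps to
    itself.
    """
    if allele == "ABSENT":
        return allele
    if allele.startswith("KIR"):
        return parse_kir_allele_name(allele).allotype
    return parse_hla_allele_name(allele).allotype
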