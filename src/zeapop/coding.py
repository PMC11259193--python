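"""Coding-sequence translation and SNP effect classification.

A :class:`CodingRegion` holds the genomic-forward sequence of a gene's exons;
the spliced CDS is the exon concatenation, reverse-complemented for
minus-strand genes.  Effects are classified by substituting the variant base
in the spliced frame and re-translating the affected codon
(synonymous / nonsynonymous / stop_gain / stop_loss); a biochemical-property
flag marks amino-acid replacements that cross a five-class partition
(nonpolar, polar-uncharged, positively charged, negatively charged, special).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .datatypes import MISSING, GenotypeDataset

__all__ = [
    "CodingRegion",
    "VariantEffect",
    "translate_cds",
    "classify_snp",
    "biochemical_change",
    "coding_variant_report",
    "BIOCHEM_CLASSES",
]

#: Amino-acid partition used for the biochemical-property flag.
BIOCHEM_CLASSES = {
    "nonpolar": set("AVLIMFW"),
    "polar_uncharged": set("STCYNQ"),
    "positive": set("KRH"),
    "negative": set("DE"),
    "special": set("GP"),
}

_AA_TO_CLASS = {aa: cls for cls, members in BIOCHEM_CLASSES.items() for aa in members}


@dataclass(frozen=True)
class CodingRegion:
    """A single-ORF coding region.

    ``genomic_seq`` is the chromosome-forward sequence starting at 1-based
    genomic coordinate ``origin``; ``exons`` are 1-based inclusive genomic
    intervals in ascending order.  For minus-strand genes codon 1 begins at
    the highest genomic coordinate after reverse-complementation.
    """

    genomic_seq: str
    origin: int
    exons: tuple
    strand: str = "+"
    chrom: str = "chr1"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for s, e in self.exons:
            if e < s:
                raise ValueError("exon end before start")
        if len(self.spliced()) % 3 != 0:
            raise ValueError("spliced CDS length must be divisible by 3")

    def spliced(self) -> str:
        """Spliced CDS on the coding strand."""
        parts = []
        for s, e in self.exons:
            lo = s - self.origin
            hi = e - self.origin + 1
            if lo < 0 or hi > len(self.genomic_seq):
                raise ValueError("exon outside provided sequence")
            parts.append(self.genomic_seq[lo:hi])
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def cds_index(self, genomic_pos: int) -> int:
        """0-based index in the spliced CDS for a genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= genomic_pos <= e:
                fwd = offset + (genomic_pos - s)
                total = sum(e2 - s2 + 1 for s2, e2 in self.exons)
                return fwd if self.strand == "+" else total - 1 - fwd
            offset += e - s + 1
        raise ValueError(f"position {genomic_pos} is non-coding")


@dataclass(frozen=True)
class VariantEffect:
    pos: int
    codon_index: int  # 0-based
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | nonsynonymous | stop_gain | stop_loss
    biochemical_change: bool


def translate_cds(region_or_seq, allow_n: bool = False) -> str:
    """Translate a spliced CDS with the standard nuclear codon table.

    Accepts a :class:`CodingRegion` (strand handled internally) or a raw
    coding-strand string; a terminal stop renders as ``*``.
    """
    seq = region_or_seq.spliced() if isinstance(region_or_seq, CodingRegion) else str(region_or_seq)
    seq = seq.upper()
    if len(seq) == 0:
        raise ValueError("empty coding sequence")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    allowed = set("ACGT") | ({"N"} if allow_n else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-ACGT bases in CDS: {sorted(bad)}")
    return str(Seq(seq).translate())


def classify_snp(region: CodingRegion, genomic_pos: int, alt_base: str) -> VariantEffect:
    """Effect of substituting ``alt_base`` (genomic forward strand) at a position."""
    alt_base = alt_base.upper()
    if alt_base not in "ACGT":
        raise ValueError("alt base must be one of ACGT")
    idx = region.cds_index(genomic_pos)  # raises "non-coding" outside exons
    cds = region.spliced()
    sub = alt_base if region.strand == "+" else str(Seq(alt_base).complement())
    codon_i = idx // 3
    within = idx % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    new_codon = codon[:within] + sub + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(new_codon).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gain"
    elif ref_aa == "*":
        effect = "stop_loss"
    else:
        effect = "nonsynonymous"
    change = (
        biochemical_change(ref_aa, alt_aa)
        if "*" not in (ref_aa, alt_aa)
        else True
    )
    return VariantEffect(
        pos=genomic_pos, codon_index=codon_i, ref_aa=ref_aa, alt_aa=alt_aa,
        effect=effect, biochemical_change=change,
    )


def biochemical_change(aa_ref: str, aa_alt: str) -> bool:
    """True iff the residues fall in different biochemical classes."""
    try:
        return _AA_TO_CLASS[aa_ref.upper()] != _AA_TO_CLASS[aa_alt.upper()]
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid code: {exc}") from exc


def coding_variant_report(
    ds: GenotypeDataset,
    region: CodingRegion,
    qual_threshold: float = 13.0103,
    min_allele_count: int = 2,
) -> pd.DataFrame:
    """Nonsingleton, nonsynonymous, property-changing variants in a region.

    Sites whose QUAL falls below ``qual_threshold`` are masked entirely (the
    dataset carries site-level confidence); surviving variants are reported
    when the alt allele is seen on ≥ ``min_allele_count`` chromosomes, the
    effect is nonsynonymous (stop gains included and labelled as such), and
    the replacement crosses biochemical classes.  Frequencies use the
    confidently called chromosomes at each site as denominator.
    """
    rows = []
    exon_lo = min(s for s, _ in region.exons)
    exon_hi = max(e for _, e in region.exons)
    for i in range(ds.n_sites):
        pos = int(ds.pos[i])
        if not (exon_lo <= pos <= exon_hi) or not ds.is_biallelic[i]:
            continue
        try:
            region.cds_index(pos)
        except ValueError:
            continue  # intronic
        if np.isfinite(ds.qual[i]) and ds.qual[i] < qual_threshold:
            continue
        g = ds.genotypes[i]
        called = g != MISSING
        n_chrom = 2 * int(called.sum())
        if n_chrom == 0:
            continue
        count = int(g[called].sum())
        if count < min_allele_count:
            continue
        eff = classify_snp(region, pos, str(ds.alt[i]))
        if eff.effect == "synonymous" or not eff.biochemical_change:
            continue
        rows.append(
            {
                "pos": pos,
                "ref": ds.ref[i],
                "alt": ds.alt[i],
                "codon_index": eff.codon_index,
                "ref_aa": eff.ref_aa,
                "alt_aa": eff.alt_aa,
                "effect": eff.effect,
                "allele_count": count,
                "n_chrom": n_chrom,
                "frequency": count / n_chrom,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pos", "ref", "alt", "codon_index", "ref_aa", "alt_aa",
                 "effect", "allele_count", "n_chrom", "frequency"],
    )
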