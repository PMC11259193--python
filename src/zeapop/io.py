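"""VCF and metadata input/output.

Writing emits minimal, valid VCF 4.2 text with unphased GT, per-genotype DP,
site QUAL, and the ancestral allele in INFO/AA, so that ``read_vcf ∘
write_vcf`` is the identity on genotypes, positions and ancestral states.
Reading goes through cyvcf2; multiallelic records and indels are kept but
flagged for exclusion rather than silently dropped.
"""

from __future__ import annotations

import numpy as np

from .datatypes import MISSING, GenotypeDataset, SampleMetadata


class VcfError(ValueError):
    pass


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, meta: SampleMetadata | None, path) -> None:
    """Write a biallelic SNP dataset as an uncompressed VCF 4.2 file."""
    samples = ds.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = dict.fromkeys(ds.chrom.tolist())
        length = ds.region_length or None
        for c in contigs:
            if length:
                fh.write(f"##contig=<ID={c},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        if not contigs and length:
            fh.write(f"##contig=<ID=chr1,length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i in range(ds.n_sites):
            qual = ds.qual[i]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            aa = ds.ancestral[i]
            info = f"AA={aa}" if aa and aa != "." else "."
            cells = []
            for j in range(ds.n_samples):
                gt = _GT_STR[int(ds.genotypes[i, j])]
                dp = int(ds.depth[i, j])
                cells.append(gt if dp == MISSING else f"{gt}:{dp}")
            fmt = "GT" if all(":" not in c for c in cells) else "GT:DP"
            if fmt == "GT:DP":
                cells = [c if ":" in c else c + ":." for c in cells]
            fh.write(
                f"{ds.chrom[i]}\t{ds.pos[i]}\t.\t{ds.ref[i]}\t{ds.alt[i]}\t"
                f"{qual_s}\t.\t{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path, metadata_path=None) -> tuple[GenotypeDataset, SampleMetadata | None]:
    """Read a VCF into a :class:`GenotypeDataset`.

    Multiallelic records and indels are read with ``is_biallelic=False`` so
    downstream filtering can count them; their dosage column encodes presence
    of the first alternate allele only.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise VcfError("cyvcf2 is required to read VCF files") from exc

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    chrom, pos, ref, alt, anc, qual, biall = [], [], [], [], [], [], []
    gts, dps = [], []
    for line_no, rec in enumerate(vcf, start=1):
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alts = rec.ALT
        alt.append(alts[0] if alts else ".")
        is_snp = (
            len(alts) == 1
            and len(rec.REF) == 1
            and len(alts[0]) == 1
            and alts[0] in "ACGT"
            and rec.REF in "ACGT"
        )
        biall.append(is_snp)
        aa = rec.INFO.get("AA")
        anc.append(aa if aa else ".")
        qual.append(rec.QUAL if rec.QUAL is not None else np.nan)
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        g = rec.gt_types.astype(np.int8)
        dosage = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, MISSING)))
        gts.append(dosage)
        try:
            d = rec.format("DP")
        except KeyError:
            d = None
        if d is None:
            dps.append(np.full(len(samples), MISSING, dtype=np.int32))
        else:
            d = d.reshape(-1).astype(np.int64)
            dps.append(np.where(d < 0, MISSING, d).astype(np.int32))

    n = len(pos)
    ds = GenotypeDataset(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        ancestral=np.array(anc, dtype=object),
        qual=np.array(qual, dtype=float),
        genotypes=(
            np.vstack(gts) if n else np.empty((0, len(samples)), dtype=np.int8)
        ),
        depth=(np.vstack(dps) if n else np.empty((0, len(samples)), dtype=np.int32)),
        samples=samples,
        is_biallelic=np.array(biall, dtype=bool),
    )

    meta = None
    if metadata_path is not None:
        meta = SampleMetadata.from_tsv(metadata_path)
        unknown = set(meta.samples) - set(samples)
        if unknown:
            raise VcfError(f"metadata samples absent from VCF: {sorted(unknown)}")
    return ds, meta
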