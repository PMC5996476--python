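"""Variant I/O: VCF read/write, site-level filters, coding-effect calls.

This module is the boundary between called genotypes and the statistics
engine.  Upstream read mapping and genotype calling are out of scope; the
pipeline starts from a multi-sample VCF of diploid genotypes.  Only
biallelic SNPs are retained (multi-allelic records and indels are skipped,
never split), and sites are filtered on their missing-call fraction with a
strict ``< max_missing_rate`` rule, optionally enforced within every
analysis group rather than cohort-wide.

Coordinates are 1-based inclusive at the VCF/GFF3 surface and 0-based
half-open internally and in BED output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from Bio.Seq import Seq

from .matrix import MISSING, GenotypeMatrix, read_metadata

log = logging.getLogger(__name__)

_NUCS = frozenset("ACGT")


def _is_biallelic_snp(ref: str, alts: tuple[str, ...]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in _NUCS
        and alts[0] in _NUCS
    )


def read_vcf(path, metadata_path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of alternate alleles in the GT field.  Half-calls
    (one missing allele) are treated as missing genotypes; records that are
    not biallelic SNPs are skipped and counted in the log.

    Raises
    ------
    ValueError
        If a VCF sample is absent from the metadata table.
    """
    meta = read_metadata(metadata_path)
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    known = set(meta["sample_id"])
    for s in vcf_samples:
        if s not in known:
            raise ValueError(f"VCF sample {s!r} missing from metadata {metadata_path}")
    meta = meta.set_index("sample_id").loc[vcf_samples].reset_index()

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    n_half = 0
    for rec in vcf:
        if not _is_biallelic_snp(rec.REF, tuple(rec.ALT)):
            n_skipped += 1
            continue
        gt = np.array(rec.genotypes, dtype=np.int64)  # (n_samples, 3): a1, a2, phased
        a1, a2 = gt[:, 0], gt[:, 1]
        dos = np.where((a1 >= 0) & (a2 >= 0), a1 + a2, MISSING).astype(np.int8)
        n_half += int(np.sum(((a1 >= 0) != (a2 >= 0))))
        if np.any(dos > 2):
            raise ValueError(f"malformed GT at {rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dos)
    if n_skipped or n_half:
        log.info("read_vcf: skipped %d non-biallelic-SNP records, %d half-calls set missing",
                 n_skipped, n_half)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(vcf_samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sites=sites, dosages=dosages, samples=meta)


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pearpop\n")
        for chrom, length in matrix.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header_samples = "\t".join(matrix.samples["sample_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{header_samples}\n")
        site_iter = matrix.sites.itertuples(index=True)
        for row in site_iter:
            gts = "\t".join(_DOSAGE_GT[int(d)] for d in matrix.dosages[:, row.Index])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def filter_variants(
    matrix: GenotypeMatrix,
    max_missing_rate: float = 0.5,
    groups: list[str] | None = None,
) -> GenotypeMatrix:
    """Retain sites with missing fraction strictly below ``max_missing_rate``.

    With ``groups`` given, a site must satisfy the rule within every listed
    group (the common-SNP rule used before the sweep scans, where a site
    must be well-genotyped in both the Asian and the European cohorts).
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    if max_missing_rate == 1.0:
        keep = np.ones(matrix.n_sites, dtype=bool)
    elif groups is None:
        keep = matrix.missing_rate() < max_missing_rate
    else:
        keep = np.ones(matrix.n_sites, dtype=bool)
        for group in groups:
            rows = matrix.group_indices(group)
            if rows.size == 0:
                raise ValueError(f"group {group!r} has no samples")
            keep &= matrix.missing_rate(rows) < max_missing_rate
    out = matrix.take_sites(keep)
    log.info("filter_variants: retained %d / %d sites (max_missing_rate=%g)",
             out.n_sites, matrix.n_sites, max_missing_rate)
    return out


# ---------------------------------------------------------------------------
# Gene models and coding-effect classification


@dataclass
class GeneModel:
    """Protein-coding gene: ordered CDS segments on one strand.

    ``cds`` holds (start, end, phase) triples, 1-based inclusive genomic
    coordinates, ordered 5'->3' along the coding strand (i.e. descending
    genomic coordinates for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        genomic = sorted((s, e) for s, e, _ in self.cds)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        if (self.coding_length - self.cds[0][2]) % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not divisible by 3 after phase")

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def coding_positions(self) -> list[int]:
        """Genomic positions in coding order (first = first transcribed base)."""
        out: list[int] = []
        for s, e, _ in self.cds:
            block = range(s, e + 1)
            out.extend(reversed(block) if self.strand == "-" else block)
        return out


def _parse_gff_attrs(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


GFF_COLUMNS = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 file into a tidy table with parsed ``ID``/``Parent``."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int},
    )
    attrs = df["attributes"].map(_parse_gff_attrs)
    df["feature_id"] = attrs.map(lambda a: a.get("ID", ""))
    df["parent"] = attrs.map(lambda a: a.get("Parent", ""))
    return df


def gene_models_from_gff3(path_or_df) -> list[GeneModel]:
    """Assemble :class:`GeneModel` objects from GFF3 CDS features.

    CDS rows are grouped by their ``Parent`` transcript; the transcript's
    ``Parent`` gene ID names the model (falling back to the transcript ID).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else read_gff3(path_or_df)
    parent_of = dict(zip(df["feature_id"], df["parent"]))
    models = []
    cds = df[df["type"] == "CDS"]
    for tx_id, sub in cds.groupby("parent", sort=False):
        strand = sub["strand"].iloc[0]
        segs = sorted(
            (int(r.start), int(r.end), 0 if r.phase == "." else int(r.phase))
            for r in sub.itertuples()
        )
        if strand == "-":
            segs = segs[::-1]
        gene_id = parent_of.get(tx_id) or tx_id
        models.append(GeneModel(gene_id=gene_id, chrom=sub["chrom"].iloc[0],
                                strand=strand, cds=segs))
    return models


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def classify_coding_effect(site, gene: GeneModel, reference: dict[str, str]) -> str:
    """Classify a SNP as ``synonymous`` / ``non-synonymous`` / ``non-coding``.

    ``site`` is a ``(chrom, pos, ref, alt)`` tuple with a 1-based position.
    The alternate base is substituted into the codon containing the site
    (reverse-complemented on minus-strand genes) and the amino acids are
    compared under the standard codon table.
    """
    chrom, pos, ref, alt = site[0], int(site[1]), site[2], site[3]
    seq = reference[chrom]
    if seq[pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: FASTA has {seq[pos - 1]}, site claims {ref}"
        )
    if chrom != gene.chrom:
        return "non-coding"
    positions = gene.coding_positions()
    try:
        cpos = positions.index(pos)
    except ValueError:
        return "non-coding"
    offset = gene.cds[0][2]  # phase of the first segment shifts the frame
    if cpos < offset:
        return "non-coding"
    codon_idx = (cpos - offset) // 3
    codon_positions = positions[offset + 3 * codon_idx: offset + 3 * codon_idx + 3]
    if len(codon_positions) < 3:
        return "non-coding"  # trailing partial codon

    def base(p: int, substitute: bool) -> str:
        b = alt if (substitute and p == pos) else seq[p - 1]
        return str(Seq(b).reverse_complement()) if gene.strand == "-" else b

    ref_codon = "".join(base(p, False) for p in codon_positions)
    alt_codon = "".join(base(p, True) for p in codon_positions)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return "synonymous" if ref_aa == alt_aa else "non-synonymous"
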