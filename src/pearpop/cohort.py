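"""Synthetic genotype cohorts with known, machine-readable truth.

The real study system — deep resequencing of >100 pear accessions across an
Asian/European divergence of several million years — is far beyond desk
scale, so every analysis in this package is exercised on simulated cohorts
that reproduce the *statistical structure* the methods assume:

* hierarchical population divergence (ancestral → region → status allele
  frequencies, a Balding–Nichols-style drift model with parameters
  ``F_region`` and ``F_status``),
* domestication diversity loss (cultivated frequencies are drifted copies
  of wild frequencies, so E[θπ_cul] = (1 − F_status)·E[θπ_wild]),
* planted selective sweeps (near-fixation of the major allele in the target
  group plus a residual tail of rare variants, so low θπ, high ROD, high
  F_ST and negative Tajima's D fire together),
* planted identity-by-descent segments (genotypes copied between a sample
  pair over an interval),
* one admixed accession assembled as a block mosaic of two cultivated donor
  pools (the *P. sinkiangensis*-like case), and
* one hypervariable locus under balancing selection, maintained as a small
  set of haplotype classes at intermediate frequency in every group (the
  S-RNase-like case).

This is a calibration model, not a demographic reconstruction: there is no
recombination-explicit coalescent and no selection through time.  The
:class:`TruthSet` records every planted feature and is the oracle for all
parameter-recovery tests downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, group_name, split_group, write_metadata
from .vcfio import write_vcf

_SPECIES_BY_GROUP = {
    "Asian_wild": "pashia",
    "Asian_cultivated": "bretschneideri",
    "European_wild": "caucasica",
    "European_cultivated": "communis",
}
ADMIXED_SPECIES = "sinkiangensis"


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    start: int  # 0-based half-open, like BED
    end: int
    target_group: str
    intensity: float = 1.0


@dataclass(frozen=True)
class IBDSpec:
    sample_a: str
    sample_b: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class AdmixtureSpec:
    sample_id: str
    donor_group_1: str
    donor_group_2: str
    proportion_1: float = 0.5
    block_length: int = 500_000


@dataclass(frozen=True)
class LDBlockSpec:
    """Founder-haplotype-pool genotype model producing block-structured LD.

    Within consecutive blocks of ``block_length`` bp each group carries only
    ``n_founders`` distinct haplotypes (drawn from the group's allele
    frequencies); every sample picks two founders per block.  Sites within a
    block are therefore strongly correlated while sites in different blocks
    are independent, so r² decays on the block-length scale.
    """

    block_length: int = 2_000
    n_founders: int = 6


@dataclass(frozen=True)
class BalancedLocusSpec:
    chrom: str
    start: int
    end: int
    n_haplotype_classes: int = 4


@dataclass
class CohortConfig:
    """Everything the simulator needs; all intervals 0-based half-open bp.

    ``snp_density`` is the expected number of simulated variant sites per
    kb before monomorphic sites are dropped.  ``F_region`` controls the
    Asian/European divergence and ``F_status`` the wild→cultivated drift
    (and hence the expected reduction of diversity, ROD ≈ F_status).
    """

    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    snp_density: float = 5.0
    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "Asian_wild": 6, "Asian_cultivated": 6,
        "European_wild": 5, "European_cultivated": 5,
    })
    F_region: float = 0.3
    F_status: float = 0.09
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    ibd_specs: list[IBDSpec] = field(default_factory=list)
    admixture_spec: AdmixtureSpec | None = None
    balanced_locus: BalancedLocusSpec | None = None
    ld_block_spec: LDBlockSpec | None = None
    missing_rate: float = 0.05
    # residual rare-variant structure inside a full-intensity sweep: the
    # fraction of sweep sites keeping a thin minor-allele tail (post-sweep
    # mutations), and that tail's frequency range.  Dense enough that every
    # 10-kb sweep window retains a few segregating rare variants — the
    # skewed spectrum that makes the diversity, differentiation and D
    # criteria fire together.
    sweep_polymorphic_fraction: float = 0.3
    sweep_residual_maf: tuple[float, float] = (0.01, 0.04)
    # ancestral alt-allele frequency spectrum, density ∝ 1/p truncated
    anc_freq_range: tuple[float, float] = (0.02, 0.98)
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for group, size in self.group_sizes.items():
            region, status = split_group(group)
            for i in range(size):
                rows.append({
                    "sample_id": f"{group}_{i:02d}", "region": region,
                    "status": status, "species": _SPECIES_BY_GROUP.get(group, "unknown"),
                })
        if self.admixture_spec is not None:
            rows.append({
                "sample_id": self.admixture_spec.sample_id, "region": "Asian",
                "status": "cultivated", "species": ADMIXED_SPECIES,
            })
        return pd.DataFrame(rows)

    def validate(self) -> None:
        lengths = self.chrom_lengths()
        for g, n in self.group_sizes.items():
            split_group(g)
            if n < 2:
                raise ValueError(f"group {g} needs >= 2 samples")
        if not (0 <= self.F_region < 1 and 0 <= self.F_status < 1):
            raise ValueError("F_region and F_status must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        sample_ids = set(self.sample_table()["sample_id"])

        def check_interval(chrom, start, end, what):
            if chrom not in lengths:
                raise ValueError(f"{what}: unknown chromosome {chrom}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"{what}: interval [{start}, {end}) outside {chrom}")

        for sw in self.sweep_specs:
            check_interval(sw.chrom, sw.start, sw.end, "sweep")
            if sw.target_group not in self.group_sizes:
                raise ValueError(f"sweep targets unknown group {sw.target_group}")
            if not 0 < sw.intensity <= 1:
                raise ValueError("sweep intensity must lie in (0, 1]")
            if self.balanced_locus is not None:
                bl = self.balanced_locus
                if sw.chrom == bl.chrom and sw.start < bl.end and bl.start < sw.end:
                    raise ValueError(
                        "sweep and balanced-locus intervals overlap; truth would be ambiguous"
                    )
        for spec in self.ibd_specs:
            check_interval(spec.chrom, spec.start, spec.end, "IBD segment")
            for s in (spec.sample_a, spec.sample_b):
                if s not in sample_ids:
                    raise ValueError(f"IBD spec names unknown sample {s}")
        if self.admixture_spec is not None:
            adm = self.admixture_spec
            for g in (adm.donor_group_1, adm.donor_group_2):
                if g not in self.group_sizes:
                    raise ValueError(f"admixture donor group {g} absent from group_sizes")
            if not 0 <= adm.proportion_1 <= 1:
                raise ValueError("admixture proportion_1 must lie in [0, 1]")
        if self.balanced_locus is not None:
            bl = self.balanced_locus
            check_interval(bl.chrom, bl.start, bl.end, "balanced locus")
            if bl.n_haplotype_classes < 2:
                raise ValueError("balanced locus needs >= 2 haplotype classes")


@dataclass
class TruthSet:
    """The simulator's record of everything it planted (BED-style frames)."""

    planted_sweeps: pd.DataFrame      # chrom start end target_group intensity
    planted_ibd: pd.DataFrame         # chrom start end sample_a sample_b
    admixture_blocks: pd.DataFrame    # chrom start end sample_id donor_group
    balanced_intervals: pd.DataFrame  # chrom start end

    def to_bed(self, frame_name: str, path) -> None:
        df = getattr(self, frame_name)
        label_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
        out = df[["chrom", "start", "end"]].copy()
        if label_cols:
            out["name"] = [
                "|".join(map(str, row))
                for row in df[label_cols].itertuples(index=False)
            ]
        else:
            out["name"] = frame_name
        out.to_csv(path, sep="\t", header=False, index=False)


def default_config(seed: int = 0) -> CohortConfig:
    """The default study conditions: 2 x 5 Mb, ~5 SNPs/kb, 23 accessions.

    Three full-intensity 100-kb sweeps (two Asian-cultivated, one
    European-cultivated), two 200-kb IBD segments, a 60/40 admixed mosaic
    accession built from the two cultivated pools, and one 50-kb balanced
    locus with four haplotype classes.
    """
    return CohortConfig(
        sweep_specs=[
            SweepSpec("chr1", 1_000_000, 1_100_000, "Asian_cultivated", 1.0),
            SweepSpec("chr1", 3_500_000, 3_600_000, "Asian_cultivated", 1.0),
            SweepSpec("chr2", 2_000_000, 2_100_000, "European_cultivated", 1.0),
        ],
        ibd_specs=[
            IBDSpec("Asian_wild_00", "Asian_wild_01", "chr1", 2_000_000, 2_200_000),
            IBDSpec("Asian_wild_00", "European_wild_00", "chr2", 1_000_000, 1_200_000),
        ],
        admixture_spec=AdmixtureSpec(
            sample_id="ADMIX_00", donor_group_1="Asian_cultivated",
            donor_group_2="European_cultivated", proportion_1=0.6,
        ),
        balanced_locus=BalancedLocusSpec("chr2", 3_000_000, 3_050_000, 4),
        seed=seed,
    )


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted allele frequencies around ``p`` with inbreeding depth F."""
    if F <= 0:
        return p.copy()
    scale = (1.0 - F) / F
    a = np.clip(p * scale, 1e-8, None)
    b = np.clip((1.0 - p) * scale, 1e-8, None)
    return rng.beta(a, b)


def _neutral_like_freqs(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Alt-allele frequencies with density ∝ 1/p on [lo, hi] (inverse-CDF draw)."""
    u = rng.random(n)
    return lo * (hi / lo) ** u


def simulate_cohort(config: CohortConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Generate a cohort and its truth set; deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = config.sample_table()
    chrom_lengths = config.chrom_lengths()
    n_samples = len(samples)

    # Plan the admixed mosaic up front: donor-group allocation is greedy on
    # bp so the realized genome proportion tracks proportion_1 to within
    # half a block, not just in expectation.
    admix_plan: dict[str, list[tuple[int, int, str, int]]] = {c: [] for c in chrom_lengths}
    if config.admixture_spec is not None:
        adm = config.admixture_spec
        donor_rows = {
            g: np.flatnonzero(
                ((samples["region"] + "_" + samples["status"]) == g).to_numpy()
                & (samples["species"] != ADMIXED_SPECIES).to_numpy()
            )
            for g in (adm.donor_group_1, adm.donor_group_2)
        }
        blocks: list[list] = []
        for chrom, length in chrom_lengths.items():
            offset = int(rng.integers(0, adm.block_length))
            for b0 in range(-offset, length, adm.block_length):
                s, e = max(b0, 0), min(b0 + adm.block_length, length)
                if s < e:
                    blocks.append([chrom, s, e])
        total_bp = sum(e - s for _, s, e in blocks)
        target = adm.proportion_1 * total_bp
        assign = [adm.donor_group_2] * len(blocks)
        acc = 0.0
        for k in rng.permutation(len(blocks)):
            size = blocks[k][2] - blocks[k][1]
            if abs(acc + size - target) < abs(acc - target):
                assign[k] = adm.donor_group_1
                acc += size
        for (chrom, s, e), g in zip(blocks, assign):
            donor = int(rng.choice(donor_rows[g]))
            admix_plan[chrom].append((s, e, g, donor))

    site_frames = []
    dosage_blocks = []
    admix_blocks: list[dict] = []
    for chrom in config.chrom_names():
        length = chrom_lengths[chrom]
        n_sites = int(round(config.snp_density * length / 1000.0))
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1

        lo, hi = config.anc_freq_range
        p_anc = _neutral_like_freqs(rng, n_sites, lo, hi)

        group_freqs: dict[str, np.ndarray] = {}
        for region in ("Asian", "European"):
            p_region = _balding_nichols(rng, p_anc, config.F_region)
            p_wild = p_region
            p_cul = _balding_nichols(rng, p_wild, config.F_status)
            group_freqs[group_name(region, "wild")] = p_wild
            group_freqs[group_name(region, "cultivated")] = p_cul

        # sweeps: push the target group toward fixation of its major allele,
        # leaving a thin tail of rare variants (post-sweep mutations)
        for sw in config.sweep_specs:
            if sw.chrom != chrom:
                continue
            p = group_freqs[sw.target_group]
            in_sweep = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
            idx = np.flatnonzero(in_sweep)
            major_is_alt = p[idx] >= 0.5
            target = major_is_alt.astype(np.float64)  # fixation of the major allele
            rare = rng.random(idx.size) < config.sweep_polymorphic_fraction
            maf = rng.uniform(*config.sweep_residual_maf, size=idx.size)
            target = np.where(rare, np.where(major_is_alt, 1.0 - maf, maf), target)
            p = p.copy()
            p[idx] = (1.0 - sw.intensity) * p[idx] + sw.intensity * target
            group_freqs[sw.target_group] = p

        # genotypes: two independent allele copies per sample, either drawn
        # directly from the group frequencies or through a founder-haplotype
        # pool when block-structured LD is requested
        dos = np.empty((n_samples, n_sites), dtype=np.int8)
        for group, size in config.group_sizes.items():
            rows = np.flatnonzero(
                ((samples["region"] + "_" + samples["status"]) == group).to_numpy()
                & (samples["species"] != ADMIXED_SPECIES).to_numpy()
            )
            p = group_freqs[group]
            if config.ld_block_spec is None:
                dos[rows] = rng.binomial(2, p[None, :], size=(rows.size, n_sites)).astype(np.int8)
            else:
                blk = config.ld_block_spec
                block_id = (pos - 1) // blk.block_length
                geno = np.zeros((rows.size, n_sites), dtype=np.int8)
                for b in np.unique(block_id):
                    cols = np.flatnonzero(block_id == b)
                    founders = (
                        rng.random((blk.n_founders, cols.size)) < p[cols][None, :]
                    ).astype(np.int8)
                    picks = rng.integers(0, blk.n_founders, size=(rows.size, 2))
                    geno[:, cols] = founders[picks[:, 0]] + founders[picks[:, 1]]
                dos[rows] = geno

        # balanced locus: a few haplotype classes at intermediate frequency,
        # identical class frequencies in every group
        if config.balanced_locus is not None and config.balanced_locus.chrom == chrom:
            bl = config.balanced_locus
            in_locus = np.flatnonzero((pos - 1 >= bl.start) & (pos - 1 < bl.end))
            K = bl.n_haplotype_classes
            # exactly half the classes carry the alternate allele at each
            # site, pinning allele frequencies near 1/2 — the deep-coalescence
            # structure of a long-lived balanced polymorphism
            base = np.zeros(K, dtype=np.int8)
            base[: K // 2 + (K % 2)] = 1
            hap_alleles = rng.permuted(
                np.tile(base, (in_locus.size, 1)), axis=1
            ).T.astype(np.int8)
            non_admixed = np.flatnonzero((samples["species"] != ADMIXED_SPECIES).to_numpy())
            classes = rng.integers(0, K, size=(non_admixed.size, 2))
            dos[np.ix_(non_admixed, in_locus)] = (
                hap_alleles[classes[:, 0]] + hap_alleles[classes[:, 1]]
            )

        # admixed accession: apply the pre-planned donor mosaic
        if config.admixture_spec is not None:
            adm = config.admixture_spec
            target_row = int(np.flatnonzero((samples["sample_id"] == adm.sample_id).to_numpy())[0])
            for s, e, g, donor in admix_plan[chrom]:
                in_block = (pos - 1 >= s) & (pos - 1 < e)
                dos[target_row, in_block] = dos[donor, in_block]
                admix_blocks.append({
                    "chrom": chrom, "start": int(s), "end": int(e),
                    "sample_id": adm.sample_id, "donor_group": g,
                })

        # planted IBD: overwrite sample_b with sample_a inside the interval
        for spec in config.ibd_specs:
            if spec.chrom != chrom:
                continue
            ia = int(np.flatnonzero((samples["sample_id"] == spec.sample_a).to_numpy())[0])
            ib = int(np.flatnonzero((samples["sample_id"] == spec.sample_b).to_numpy())[0])
            in_seg = (pos - 1 >= spec.start) & (pos - 1 < spec.end)
            dos[ib, in_seg] = dos[ia, in_seg]

        if config.missing_rate > 0:
            drop = rng.random(dos.shape) < config.missing_rate
            dos[drop] = MISSING

        # draw ref/alt bases, alt differing from ref
        bases = np.array(list("ACGT"))
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        site_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": bases[ref_idx], "alt": bases[alt_idx],
        }))
        dosage_blocks.append(dos)

    sites = pd.concat(site_frames, ignore_index=True)
    dosages = np.concatenate(dosage_blocks, axis=1)

    # keep only sites still segregating cohort-wide
    called = dosages >= 0
    alt = np.where(called, dosages, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    keep = (alt > 0) & (alt < total)
    matrix = GenotypeMatrix(
        sites=sites.loc[keep], dosages=dosages[:, keep],
        samples=samples, chrom_lengths=chrom_lengths,
    )

    truth = TruthSet(
        planted_sweeps=pd.DataFrame(
            [asdict(s) for s in config.sweep_specs],
            columns=["chrom", "start", "end", "target_group", "intensity"],
        ),
        planted_ibd=pd.DataFrame(
            [asdict(s) for s in config.ibd_specs],
            columns=["sample_a", "sample_b", "chrom", "start", "end"],
        )[["chrom", "start", "end", "sample_a", "sample_b"]],
        admixture_blocks=pd.DataFrame(
            admix_blocks, columns=["chrom", "start", "end", "sample_id", "donor_group"],
        ),
        balanced_intervals=pd.DataFrame(
            [asdict(config.balanced_locus)] if config.balanced_locus else [],
            columns=["chrom", "start", "end", "n_haplotype_classes"],
        )[["chrom", "start", "end"]],
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Fixture emission


def _toy_gene_rows(gene_id: str, chrom: str, start: int, strand: str) -> list[str]:
    """A compact two-exon gene: UTRs, CDS split by one intron; 1-based GFF3."""
    # layout (bp, relative): 5'UTR 200 | CDS 900 | intron 1000 | CDS 600 | 3'UTR 300
    utr5 = (start, start + 199)
    cds1 = (start + 200, start + 1099)
    intron_end = start + 2099
    cds2 = (intron_end + 1, intron_end + 600)
    utr3 = (cds2[1] + 1, cds2[1] + 300)
    gene = (utr5[0], utr3[1])
    exon1 = (utr5[0], cds1[1])
    exon2 = (cds2[0], utr3[1])
    mrna_id = f"{gene_id}.t1"

    def row(ftype, iv, attrs, phase="."):
        return f"{chrom}\tpearpop\t{ftype}\t{iv[0]}\t{iv[1]}\t.\t{strand}\t{phase}\t{attrs}"

    rows = [
        row("gene", gene, f"ID={gene_id}"),
        row("mRNA", gene, f"ID={mrna_id};Parent={gene_id}"),
        row("exon", exon1, f"ID={mrna_id}.e1;Parent={mrna_id}"),
        row("exon", exon2, f"ID={mrna_id}.e2;Parent={mrna_id}"),
    ]
    if strand == "+":
        rows += [
            row("five_prime_UTR", utr5, f"Parent={mrna_id}"),
            row("CDS", cds1, f"ID={mrna_id}.c1;Parent={mrna_id}", "0"),
            row("CDS", cds2, f"ID={mrna_id}.c2;Parent={mrna_id}", "0"),
            row("three_prime_UTR", utr3, f"Parent={mrna_id}"),
        ]
    else:
        rows += [
            row("three_prime_UTR", utr5, f"Parent={mrna_id}"),
            row("CDS", cds1, f"ID={mrna_id}.c1;Parent={mrna_id}", "0"),
            row("CDS", cds2, f"ID={mrna_id}.c2;Parent={mrna_id}", "0"),
            row("five_prime_UTR", utr3, f"Parent={mrna_id}"),
        ]
    return rows


def write_toy_gff3(chrom_lengths: dict[str, int], path, gene_spacing: int = 50_000) -> None:
    """Tile two-exon genes along the genome every ``gene_spacing`` bp."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        counter = 0
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
            start = 10_001
            while start + 3_000 < length:
                counter += 1
                strand = "+" if counter % 2 else "-"
                for line in _toy_gene_rows(f"gene{counter:04d}", chrom, start, strand):
                    fh.write(line + "\n")
                start += gene_spacing


def write_qtl_bed(
    truth: TruthSet,
    chrom_lengths: dict[str, int],
    path,
    overlap_fraction: float = 1.0,
    n_decoys_per_chrom: int = 3,
    margin: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """QTL intervals overlapping a chosen fraction of the planted sweeps.

    The first ``ceil(overlap_fraction * n_sweeps)`` sweeps each receive a
    QTL extending ``margin`` bp past both sweep edges; decoy QTLs are placed
    in sweep-free territory so that ``overlap_fraction = 0`` yields strictly
    zero intersection with the truth sweep set.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sweeps = truth.planted_sweeps
    n_cover = int(np.ceil(overlap_fraction * len(sweeps)))
    rows = []
    for _, sw in sweeps.iloc[:n_cover].iterrows():
        rows.append({
            "chrom": sw["chrom"],
            "start": max(0, int(sw["start"]) - margin),
            "end": min(chrom_lengths[sw["chrom"]], int(sw["end"]) + margin),
            "name": "qtl_on_sweep",
        })
    qtl_len = 100_000
    for chrom, length in chrom_lengths.items():
        placed = 0
        attempts = 0
        while placed < n_decoys_per_chrom and attempts < 1000:
            attempts += 1
            start = int(rng.integers(0, max(1, length - qtl_len)))
            end = start + qtl_len
            clash = any(
                sw["chrom"] == chrom and start < int(sw["end"]) + margin
                and int(sw["start"]) - margin < end
                for _, sw in sweeps.iterrows()
            )
            if not clash:
                rows.append({"chrom": chrom, "start": start, "end": end, "name": "qtl_decoy"})
                placed += 1
    qtl = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    qtl.to_csv(path, sep="\t", header=False, index=False)
    return qtl


def emit_fixture(
    matrix: GenotypeMatrix,
    truth: TruthSet,
    out_dir,
    qtl_overlap_fraction: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """Write the full plain-text fixture set for one simulated cohort.

    Emits a VCF, the sample-metadata TSV, truth BEDs for sweeps / IBD /
    admixture / the balanced locus, a toy GFF3 gene annotation tiled over
    the genome, a QTL BED and a chromosome-sizes TSV.  Returns the file map.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "metadata": os.path.join(out_dir, "samples.tsv"),
        "truth_sweeps": os.path.join(out_dir, "truth_sweeps.bed"),
        "truth_ibd": os.path.join(out_dir, "truth_ibd.bed"),
        "truth_admixture": os.path.join(out_dir, "truth_admixture.bed"),
        "truth_balanced": os.path.join(out_dir, "truth_balanced.bed"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "qtl": os.path.join(out_dir, "qtl.bed"),
        "chrom_sizes": os.path.join(out_dir, "chrom_sizes.tsv"),
    }
    write_vcf(matrix, paths["vcf"])
    write_metadata(matrix.samples, paths["metadata"])
    truth.to_bed("planted_sweeps", paths["truth_sweeps"])
    truth.to_bed("planted_ibd", paths["truth_ibd"])
    truth.to_bed("admixture_blocks", paths["truth_admixture"])
    truth.to_bed("balanced_intervals", paths["truth_balanced"])
    write_toy_gff3(matrix.chrom_lengths, paths["gff3"])
    write_qtl_bed(truth, matrix.chrom_lengths, paths["qtl"],
                  overlap_fraction=qtl_overlap_fraction, seed=seed)
    pd.DataFrame(
        {"chrom": list(matrix.chrom_lengths), "length": list(matrix.chrom_lengths.values())}
    ).to_csv(paths["chrom_sizes"], sep="\t", header=False, index=False)
    return paths
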