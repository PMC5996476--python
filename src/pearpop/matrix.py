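"""Core genotype container shared by every analysis module.

The substrate of all statistics in this package is a samples x sites matrix
of diploid allele-dosage calls (0, 1, 2 copies of the alternate allele, or
missing) together with site coordinates and per-sample group labels
(geographic region x domestication status, plus a species tag).  Groups are
addressed by ``"<region>_<status>"`` strings, e.g. ``"Asian_cultivated"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

REGIONS = ("Asian", "European")
STATUSES = ("wild", "cultivated")

SAMPLE_COLUMNS = ["sample_id", "region", "status", "species"]


def group_name(region: str, status: str) -> str:
    return f"{region}_{status}"


def split_group(group: str) -> tuple[str, str]:
    """Split ``"Asian_wild"`` into ``("Asian", "wild")``, validating both parts."""
    region, _, status = group.partition("_")
    if region not in REGIONS or status not in STATUSES:
        raise ValueError(
            f"unknown group {group!r}; expected <region>_<status> with "
            f"region in {REGIONS} and status in {STATUSES}"
        )
    return region, status


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with site coordinates and sample metadata.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom, pos, ref, alt``; ``pos`` is 1-based and strictly
        increasing within each chromosome; every site is a biallelic SNP.
    dosages : numpy.ndarray of int8, shape (n_samples, n_sites)
        Count of alternate alleles per call; ``MISSING`` (-1) for no-calls.
    samples : pandas.DataFrame
        Columns ``sample_id, region, status, species``.
    chrom_lengths : dict
        Chromosome sizes in bp.  When unknown (e.g. a bare VCF), inferred as
        the last site position per chromosome.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    samples: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        bad = ~self.samples["region"].isin(REGIONS)
        if bad.any():
            raise ValueError(
                f"unknown region labels: {sorted(self.samples.loc[bad, 'region'].unique())}"
            )
        bad = ~self.samples["status"].isin(STATUSES)
        if bad.any():
            raise ValueError(
                f"unknown status labels: {sorted(self.samples.loc[bad, 'status'].unique())}"
            )
        if not self.chrom_lengths:
            self.chrom_lengths = {
                chrom: int(sub["pos"].max())
                for chrom, sub in self.sites.groupby("chrom", sort=False)
            }

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero((self.samples["sample_id"] == sample_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        return int(idx[0])

    def group_indices(self, group: str, exclude_species: tuple[str, ...] = ()) -> np.ndarray:
        """Row indices of samples in a ``<region>_<status>`` group.

        ``exclude_species`` drops e.g. admixed accessions from a scan, the
        way admixed genotypes are removed before sweep detection.
        """
        region, status = split_group(group)
        mask = (self.samples["region"] == region) & (self.samples["status"] == status)
        for sp in exclude_species:
            mask &= self.samples["species"] != sp
        return np.flatnonzero(mask.to_numpy())

    def group_dosages(self, group: str, exclude_species: tuple[str, ...] = ()) -> np.ndarray:
        return self.dosages[self.group_indices(group, exclude_species)]

    # -- subsetting --------------------------------------------------------

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx],
            dosages=self.dosages[:, idx],
            samples=self.samples,
            chrom_lengths=dict(self.chrom_lengths),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sites=self.sites,
            dosages=self.dosages[index],
            samples=self.samples.iloc[index],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def site_selector(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())

    # -- per-site summaries ------------------------------------------------

    def allele_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele copies, called allele copies) over ``rows``."""
        d = self.dosages if rows is None else self.dosages[rows]
        called = d >= 0
        alt = np.where(called, d, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return alt.astype(np.int64), total.astype(np.int64)

    def missing_rate(self, rows: np.ndarray | None = None) -> np.ndarray:
        d = self.dosages if rows is None else self.dosages[rows]
        return (d < 0).mean(axis=0)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (``sample_id region status species``)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata {path} lacks columns {missing_cols}")
    return meta[SAMPLE_COLUMNS]


def write_metadata(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)
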