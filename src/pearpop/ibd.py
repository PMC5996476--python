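"""Windowed identity-by-descent profiling and ancestry painting.

IBD between two accessions is proxied by genotype similarity in contiguous
non-overlapping 10-kb windows: the per-site distance between unphased
diploids is the allele-content difference |dosage_i − dosage_j| / 2 (the
p-distance interpretation for dosage data, under which two heterozygotes
are at distance 0), similarity is one minus its mean over co-called sites,
and a window is an IBD window when its similarity exceeds 0.95.  Windows
with 10 or fewer co-called SNPs are non-evaluable and never enter any
denominator.  P_ij is the percentage of IBD windows among evaluable windows
genome-wide, and AverIBD averages P_ij over the (group x reference-set)
pairs, excluding self-pairs.

Ancestry painting assigns each window of a target accession to whichever
of two donor pools contains its most similar member, provided that best
similarity itself passes the IBD criterion — the chromosome-mosaic view
used to demonstrate the hybrid origin of *P. sinkiangensis*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import IBD_WINDOWS, WindowSpec, window_grid
from .matrix import GenotypeMatrix

MIN_SNPS = 10          # windows need strictly more co-called SNPs than this
SIMILARITY_CUT = 0.95  # IBD requires similarity strictly above this


def pair_similarity(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Similarity = 1 − mean |d_i − d_j|/2 over co-called sites; NaN if none."""
    dos_i = np.asarray(dos_i)
    dos_j = np.asarray(dos_j)
    both = (dos_i >= 0) & (dos_j >= 0)
    if not both.any():
        return np.nan
    dist = np.abs(dos_i[both].astype(np.float64) - dos_j[both]) / 2.0
    return 1.0 - float(dist.mean())


@dataclass
class IBDProfile:
    sample_i: str
    sample_j: str
    windows: pd.DataFrame  # chrom start end n_snps similarity evaluable ibd
    p_ij: float            # percent of IBD windows among evaluable windows


def _window_sums(matrix: GenotypeMatrix, values: np.ndarray, counts: np.ndarray,
                 grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sum ``values`` and ``counts`` (per site) over each grid window."""
    val_out = np.zeros(len(grid))
    cnt_out = np.zeros(len(grid), dtype=np.int64)
    for chrom, sub in grid.groupby("chrom", sort=False):
        sel = matrix.site_selector(chrom)
        pos0 = matrix.sites["pos"].to_numpy()[sel] - 1
        i0 = np.searchsorted(pos0, sub["start"].to_numpy(), side="left")
        i1 = np.searchsorted(pos0, sub["end"].to_numpy(), side="left")
        cs_v = np.concatenate([[0.0], np.cumsum(values[sel])])
        cs_c = np.concatenate([[0], np.cumsum(counts[sel])])
        val_out[sub.index] = cs_v[i1] - cs_v[i0]
        cnt_out[sub.index] = cs_c[i1] - cs_c[i0]
    return val_out, cnt_out


def pair_ibd_profile(
    matrix: GenotypeMatrix, sample_i: str, sample_j: str,
    spec: WindowSpec = IBD_WINDOWS,
) -> IBDProfile:
    """Windowed similarity profile and genome-wide IBD percentage P_ij."""
    di = matrix.dosages[matrix.sample_index(sample_i)].astype(np.int64)
    dj = matrix.dosages[matrix.sample_index(sample_j)].astype(np.int64)
    both = (di >= 0) & (dj >= 0)
    dist = np.where(both, np.abs(di - dj) / 2.0, 0.0)
    grid = window_grid(matrix.chrom_lengths, spec)
    dist_sum, n_snps = _window_sums(matrix, dist, both.astype(np.int64), grid)

    with np.errstate(divide="ignore", invalid="ignore"):
        similarity = 1.0 - dist_sum / n_snps
    similarity[n_snps == 0] = np.nan
    evaluable = n_snps > MIN_SNPS
    ibd = evaluable & (similarity > SIMILARITY_CUT)
    windows = grid.copy()
    windows["n_snps"] = n_snps
    windows["similarity"] = similarity
    windows["evaluable"] = evaluable
    windows["ibd"] = ibd
    p_ij = 100.0 * ibd.sum() / evaluable.sum() if evaluable.any() else np.nan
    return IBDProfile(sample_i=sample_i, sample_j=sample_j, windows=windows, p_ij=p_ij)


def ibd_matrix(
    matrix: GenotypeMatrix,
    sample_ids: list[str] | None = None,
    spec: WindowSpec = IBD_WINDOWS,
) -> pd.DataFrame:
    """Symmetric table of P_ij over all sample pairs (NaN diagonal)."""
    ids = sample_ids or list(matrix.samples["sample_id"])
    out = pd.DataFrame(np.nan, index=ids, columns=ids)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            p = pair_ibd_profile(matrix, ids[a], ids[b], spec).p_ij
            out.iloc[a, b] = out.iloc[b, a] = p
    return out


@dataclass
class IBDGroupSummary:
    group: str
    reference_set: str
    n: int
    m: int
    k: int
    aver_ibd: float


def aver_ibd(
    pij: pd.DataFrame,
    group_samples: list[str],
    reference_samples: list[str],
    group: str = "group",
    reference_set: str = "reference",
) -> IBDGroupSummary:
    """AverIBD = (1/k) ΣΣ P_ij over group x reference pairs, self-pairs excluded."""
    values = []
    for i in group_samples:
        for j in reference_samples:
            if i == j:
                continue
            v = pij.loc[i, j]
            if not np.isnan(v):
                values.append(float(v))
    if not values:
        raise ValueError("no non-missing P_ij pairs between group and reference set")
    return IBDGroupSummary(
        group=group, reference_set=reference_set,
        n=len(group_samples), m=len(reference_samples),
        k=len(values), aver_ibd=float(np.mean(values)),
    )


@dataclass
class PaintResult:
    target: str
    donor_a: str
    donor_b: str
    windows: pd.DataFrame          # chrom start end label in {A-label, B-label, unassigned}
    proportions: dict[str, float]  # percent of evaluable windows per label


def paint_ancestry(
    matrix: GenotypeMatrix,
    target: str,
    donor_group_a: str,
    donor_group_b: str,
    spec: WindowSpec = IBD_WINDOWS,
    exclude_species: tuple[str, ...] = (),
) -> PaintResult:
    """Assign each window of ``target`` to its most similar donor pool.

    For each evaluable window the maximum similarity of the target to any
    member of each pool is computed; the window is labeled with the pool
    holding the higher maximum when that maximum passes the IBD similarity
    cut, and left unassigned otherwise (ties included).  The target must
    not belong to either donor pool.
    """
    rows_a = matrix.group_indices(donor_group_a, exclude_species)
    rows_b = matrix.group_indices(donor_group_b, exclude_species)
    t_idx = matrix.sample_index(target)
    if t_idx in rows_a or t_idx in rows_b:
        raise ValueError(f"target {target} is a member of a donor group")
    if rows_a.size == 0 or rows_b.size == 0:
        raise ValueError("donor groups must be non-empty")

    grid = window_grid(matrix.chrom_lengths, spec)
    dt = matrix.dosages[t_idx].astype(np.int64)

    def pool_max(rows: np.ndarray) -> np.ndarray:
        best = np.full(len(grid), np.nan)
        for r in rows:
            dr = matrix.dosages[r].astype(np.int64)
            both = (dt >= 0) & (dr >= 0)
            dist = np.where(both, np.abs(dt - dr) / 2.0, 0.0)
            dist_sum, n_snps = _window_sums(matrix, dist, both.astype(np.int64), grid)
            with np.errstate(divide="ignore", invalid="ignore"):
                sim = 1.0 - dist_sum / n_snps
            sim[n_snps <= MIN_SNPS] = np.nan
            best = np.fmax(best, sim)
        return best

    best_a = pool_max(rows_a)
    best_b = pool_max(rows_b)
    evaluable = ~(np.isnan(best_a) & np.isnan(best_b))
    a_wins = np.fmax(best_a, -np.inf) > np.fmax(best_b, -np.inf)
    b_wins = np.fmax(best_b, -np.inf) > np.fmax(best_a, -np.inf)
    best = np.fmax(best_a, best_b)
    assigned = evaluable & (best > SIMILARITY_CUT)
    label = np.where(assigned & a_wins, donor_group_a,
                     np.where(assigned & b_wins, donor_group_b, "unassigned"))
    windows = grid.copy()
    windows["evaluable"] = evaluable
    windows["label"] = np.where(evaluable, label, "non-evaluable")
    n_eval = int(evaluable.sum())
    props = {
        donor_group_a: 100.0 * np.sum(evaluable & (label == donor_group_a)) / n_eval,
        donor_group_b: 100.0 * np.sum(evaluable & (label == donor_group_b)) / n_eval,
        "unassigned": 100.0 * np.sum(evaluable & (label == "unassigned")) / n_eval,
    } if n_eval else {}
    return PaintResult(target=target, donor_a=donor_group_a, donor_b=donor_group_b,
                       windows=windows, proportions=props)
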