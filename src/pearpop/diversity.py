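"""Windowed population-genetic statistics.

Implements the window-level quantities the domestication scans are built
on: nucleotide diversity θπ (mean pairwise difference per site), Watterson's
θw (from the segregating-site count S), Tajima's D (the normalized
difference between the two), Hudson-style pairwise F_ST between groups, the
reduction-of-diversity statistic ROD = 1 − θπ_cul/θπ_wild, per-feature-class
diversity, and the d/2T evolution-rate estimator for genes under long-term
balancing selection.

Windows default to 10 kb with a 5-kb step for diversity scans and to
non-overlapping 10-kb windows for selection scans.  All genotype input is
unphased diploid dosage with pairwise deletion of missing calls:

* θπ uses the exact per-site number of called allele copies C and alt
  copies c: per-site π = 2c(C−c) / (C(C−1)), the mean difference over all
  C-choose-2 chromosome pairs.
* θw and Tajima's D need a single sample size per window; the rounded
  harmonic mean of per-site C is used (Tajima's variance constants assume
  fixed n — a documented approximation under missingness).

Per-site normalization divides by the window length in bp by default; a
per-window callable-site count can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (sizes in bp)."""

    window_size: int = 10_000
    step: int = 5_000
    min_snps: int = 1

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0 or self.min_snps < 0:
            raise ValueError("window_size, step must be positive; min_snps >= 0")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")


SWEEP_WINDOWS = WindowSpec(window_size=10_000, step=10_000)
IBD_WINDOWS = WindowSpec(window_size=10_000, step=10_000, min_snps=11)


@dataclass(frozen=True)
class RateEstimate:
    """Per-site substitution-rate estimate d / (2T).

    ``d`` is the nucleotide diversity of the locus and ``T`` the time in
    years since divergence from the most recent common ancestor; the factor
    2 accounts for the two lineages separating the sampled alleles.
    """

    d: float
    T: float

    @property
    def rate(self) -> float:
        return self.d / (2.0 * self.T)


def evolution_rate(d: float, T: float) -> RateEstimate:
    if T <= 0:
        raise ValueError("divergence time T must be positive")
    if d < 0:
        raise ValueError("diversity d must be non-negative")
    return RateEstimate(d=d, T=T)


# ---------------------------------------------------------------------------
# Window grids


def window_grid(chrom_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """All windows over the genome; 0-based half-open [start, end)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, spec.step)
        ends = np.minimum(starts + spec.window_size, length)
        keep = ends > starts
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": ends[keep]}))
    return pd.concat(rows, ignore_index=True)


def _window_site_slices(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Index ranges of 1-based positions falling in half-open windows."""
    pos0 = pos - 1
    i0 = np.searchsorted(pos0, starts, side="left")
    i1 = np.searchsorted(pos0, ends, side="left")
    return i0, i1


# ---------------------------------------------------------------------------
# Tajima's D constants

_MAX_HARMONIC = 4096
_H1 = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, _MAX_HARMONIC))])
_H2 = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, _MAX_HARMONIC) ** 2)])


def tajima_constants(n: int) -> dict[str, float]:
    """Standard a1, a2, b1, b2, c1, c2, e1, e2 for sample size n chromosomes."""
    if n < 2:
        raise ValueError("Tajima's constants require n >= 2")
    a1 = float(_H1[n - 1])
    a2 = float(_H2[n - 1])
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(pi_count: float, S: int, n: int) -> float:
    """Tajima's D from the pairwise-difference sum, S and sample size n."""
    if S == 0 or n < 2:
        return np.nan
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:  # degenerate at n = 2, where the variance vanishes
        return np.nan
    return (pi_count - S / k["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Per-site building blocks


def per_site_pi(alt: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Mean pairwise difference per site: 2c(C−c)/(C(C−1)); 0 where C < 2."""
    alt = alt.astype(np.float64)
    total = total.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (total - alt) / (total * (total - 1.0))
    pi[total < 2] = 0.0
    return pi


def window_diversity(
    matrix: GenotypeMatrix,
    group: str,
    spec: WindowSpec = WindowSpec(),
    callable_sites: pd.DataFrame | None = None,
    exclude_species: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Windowed θπ, θw and Tajima's D for one group.

    Returns one row per window: ``chrom start end group S n_chrom
    theta_pi_count theta_pi theta_w tajima_d L n_sites``.  Windows holding
    fewer than ``spec.min_snps`` segregating sites get missing (NaN)
    statistics.  ``callable_sites`` may supply a per-window effective length
    ``L`` (columns ``chrom start end L`` on the same grid) replacing the
    default window length in bp.
    """
    rows = matrix.group_indices(group, exclude_species)
    if rows.size < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples, has {rows.size}")
    alt, total = matrix.allele_counts(rows)
    pi = per_site_pi(alt, total)
    seg = ((alt > 0) & (alt < total)).astype(np.float64)
    usable = total >= 2
    inv_total = np.where(usable, 1.0 / np.maximum(total, 1), 0.0)

    grid = window_grid(matrix.chrom_lengths, spec)
    out = grid.copy()
    S_col = np.zeros(len(grid))
    pi_count_col = np.zeros(len(grid))
    n_col = np.zeros(len(grid), dtype=np.int64)
    nsites_col = np.zeros(len(grid), dtype=np.int64)

    for chrom in matrix.chroms:
        sel = matrix.site_selector(chrom)
        pos = matrix.sites["pos"].to_numpy()[sel]
        gmask = (grid["chrom"] == chrom).to_numpy()
        i0, i1 = _window_site_slices(pos, grid.loc[gmask, "start"].to_numpy(),
                                     grid.loc[gmask, "end"].to_numpy())
        cs = np.concatenate(  # cumulative sums padded with leading zero
            [[0.0], np.cumsum(pi[sel])]), np.concatenate([[0.0], np.cumsum(seg[sel])])
        cs_pi, cs_seg = cs
        cs_inv = np.concatenate([[0.0], np.cumsum(inv_total[sel])])
        cs_use = np.concatenate([[0.0], np.cumsum(usable[sel].astype(np.float64))])
        pi_count_col[gmask] = cs_pi[i1] - cs_pi[i0]
        S_col[gmask] = cs_seg[i1] - cs_seg[i0]
        nsites_col[gmask] = (cs_use[i1] - cs_use[i0]).astype(np.int64)
        inv_sum = cs_inv[i1] - cs_inv[i0]
        with np.errstate(divide="ignore", invalid="ignore"):
            harm = (cs_use[i1] - cs_use[i0]) / inv_sum
        n_col[gmask] = np.where(inv_sum > 0, np.round(harm), 0).astype(np.int64)

    if callable_sites is not None:
        merged = grid.merge(callable_sites, on=["chrom", "start", "end"], how="left")
        if merged["L"].isna().any():
            raise ValueError("callable_sites grid does not cover every window")
        L = merged["L"].to_numpy(dtype=np.float64)
    else:
        L = (grid["end"] - grid["start"]).to_numpy(dtype=np.float64)

    S_int = S_col.astype(np.int64)
    a1 = np.where(n_col >= 2, _H1[np.maximum(n_col - 1, 1)], np.nan)
    theta_w = np.where(S_int > 0, S_col / a1, 0.0) / L
    theta_pi = pi_count_col / L
    tajd = np.full(len(grid), np.nan)
    for i in np.flatnonzero((S_int > 0) & (n_col >= 2)):
        tajd[i] = tajima_d(pi_count_col[i], int(S_int[i]), int(n_col[i]))

    low = S_int < spec.min_snps
    out["group"] = group
    out["S"] = S_int
    out["n_chrom"] = n_col
    out["theta_pi_count"] = pi_count_col
    out["theta_pi"] = theta_pi
    out["theta_w"] = np.where(np.isnan(theta_w) & (S_int == 0), 0.0, theta_w)
    out["tajima_d"] = tajd
    out["L"] = L
    out["n_sites"] = nsites_col
    if spec.min_snps > 0:
        out.loc[low & (S_int > 0), ["theta_pi", "theta_w", "tajima_d"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# F_ST


def hudson_fst_components(
    alt1: np.ndarray, tot1: np.ndarray, alt2: np.ndarray, tot2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson estimator numerator/denominator and a usability mask.

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

    Sites with < 2 called copies in either group, or monomorphic for the
    same allele in both groups (den = 0), are unusable.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / tot1
        p2 = alt2 / tot2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (tot1 - 1) - p2 * (1 - p2) / (tot2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (tot1 >= 2) & (tot2 >= 2) & (den > 0)
    return num, den, ok


def _wc84_components(d1: np.ndarray, d2: np.ndarray):
    """Weir–Cockerham (1984) per-site a, b, c variance components (r = 2)."""
    comps = []
    for d in (d1, d2):
        called = d >= 0
        n = called.sum(axis=0).astype(np.float64)
        alt = np.where(called, d, 0).sum(axis=0)
        het = ((d == 1).sum(axis=0)).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            comps.append((n, alt / (2 * n), het / n))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    ok = (n1 >= 2) & (n2 >= 2) & ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    return a, b, c, ok


def window_fst(
    matrix: GenotypeMatrix,
    group_a: str,
    group_b: str,
    spec: WindowSpec = SWEEP_WINDOWS,
    estimator: str = "hudson",
    exclude_species: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Windowed pairwise F_ST as a ratio of averages.

    Hudson/Bhatia (default) sums per-site numerators and denominators over
    the window; ``estimator="wc84"`` uses Weir–Cockerham (1984) variance
    components instead.  Windows with no usable site get NaN.  Negative
    estimates are reported as-is.
    """
    rows_a = matrix.group_indices(group_a, exclude_species)
    rows_b = matrix.group_indices(group_b, exclude_species)
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError("both groups need >= 2 samples")
    if estimator == "hudson":
        alt1, tot1 = matrix.allele_counts(rows_a)
        alt2, tot2 = matrix.allele_counts(rows_b)
        num, den, ok = hudson_fst_components(alt1, tot1, alt2, tot2)
    elif estimator == "wc84":
        num, den_b, den_c, ok = _wc84_components(
            matrix.dosages[rows_a].astype(np.int64), matrix.dosages[rows_b].astype(np.int64)
        )
        den = num + den_b + den_c
    else:
        raise ValueError(f"unknown F_ST estimator {estimator!r}")
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)

    grid = window_grid(matrix.chrom_lengths, spec)
    fst = np.full(len(grid), np.nan)
    for chrom in matrix.chroms:
        sel = matrix.site_selector(chrom)
        pos = matrix.sites["pos"].to_numpy()[sel]
        gmask = (grid["chrom"] == chrom).to_numpy()
        i0, i1 = _window_site_slices(pos, grid.loc[gmask, "start"].to_numpy(),
                                     grid.loc[gmask, "end"].to_numpy())
        cs_num = np.concatenate([[0.0], np.cumsum(num[sel])])
        cs_den = np.concatenate([[0.0], np.cumsum(den[sel])])
        cs_ok = np.concatenate([[0.0], np.cumsum(ok[sel].astype(np.float64))])
        wnum = cs_num[i1] - cs_num[i0]
        wden = cs_den[i1] - cs_den[i0]
        wok = cs_ok[i1] - cs_ok[i0]
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = wnum / wden
        fst[gmask] = np.where((wok > 0) & (wden != 0), vals, np.nan)
    out = grid.copy()
    out["group_a"] = group_a
    out["group_b"] = group_b
    out["fst"] = fst
    return out


def window_rod(div_cultivated: pd.DataFrame, div_wild: pd.DataFrame) -> pd.DataFrame:
    """ROD = 1 − θπ_cul/θπ_wild per window; NaN where θπ_wild = 0."""
    key = ["chrom", "start", "end"]
    if not div_cultivated[key].reset_index(drop=True).equals(
        div_wild[key].reset_index(drop=True)
    ):
        raise ValueError("window grids of the two diversity tables differ")
    pi_c = div_cultivated["theta_pi"].to_numpy(dtype=np.float64)
    pi_w = div_wild["theta_pi"].to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        rod = 1.0 - pi_c / pi_w
    rod[pi_w == 0] = np.nan
    out = div_cultivated[key].copy()
    out["rod"] = rod
    return out


# ---------------------------------------------------------------------------
# Diversity per annotation feature class

FEATURE_PRECEDENCE = ["CDS", "UTR", "intron", "mRNA", "intergenic"]
_UTR_TYPES = ("five_prime_UTR", "three_prime_UTR", "UTR")


def _paint_classes(gff: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    """Per-bp class codes (index into FEATURE_PRECEDENCE) for one chromosome.

    The chromosome is painted in reverse precedence order so that higher
    classes overwrite lower ones; introns are mRNA spans minus exons.
    """
    code = np.full(length, FEATURE_PRECEDENCE.index("intergenic"), dtype=np.int8)
    sub = gff[gff["chrom"] == chrom]

    def paint(types: tuple[str, ...], cls: str) -> None:
        cid = FEATURE_PRECEDENCE.index(cls)
        for row in sub[sub["type"].isin(types)].itertuples():
            code[row.start - 1: row.end] = cid

    paint(("mRNA",), "mRNA")
    # introns: mRNA span minus exon union
    exon_mask = np.zeros(length, dtype=bool)
    for row in sub[sub["type"] == "exon"].itertuples():
        exon_mask[row.start - 1: row.end] = True
    for row in sub[sub["type"] == "mRNA"].itertuples():
        span = slice(row.start - 1, row.end)
        intron_here = ~exon_mask[span]
        seg = code[span]
        seg[intron_here] = FEATURE_PRECEDENCE.index("intron")
        code[span] = seg
    paint(_UTR_TYPES, "UTR")
    paint(("CDS",), "CDS")
    return code


def diversity_by_feature(
    matrix: GenotypeMatrix,
    group: str,
    gff: pd.DataFrame,
    classes: list[str] | None = None,
    exclude_species: tuple[str, ...] = (),
) -> pd.DataFrame:
    """θπ/θw/Tajima's D per annotation class (CDS > UTR > intron > mRNA > intergenic).

    Every site is assigned to exactly one class by precedence; the per-site
    denominator L is the genomic bp painted with that class.
    """
    classes = classes or FEATURE_PRECEDENCE
    unknown = set(classes) - set(FEATURE_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown feature classes {sorted(unknown)}")
    rows = matrix.group_indices(group, exclude_species)
    if rows.size < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples")
    alt, total = matrix.allele_counts(rows)
    pi = per_site_pi(alt, total)
    seg = (alt > 0) & (alt < total)

    site_class = np.empty(matrix.n_sites, dtype=np.int8)
    class_len = np.zeros(len(FEATURE_PRECEDENCE), dtype=np.int64)
    for chrom in matrix.chroms:
        length = matrix.chrom_lengths[chrom]
        code = _paint_classes(gff, chrom, length)
        class_len += np.bincount(code, minlength=len(FEATURE_PRECEDENCE))
        sel = matrix.site_selector(chrom)
        site_class[sel] = code[matrix.sites["pos"].to_numpy()[sel] - 1]

    records = []
    for cls in classes:
        cid = FEATURE_PRECEDENCE.index(cls)
        mask = site_class == cid
        L = float(class_len[cid])
        S = int(seg[mask].sum())
        pi_count = float(pi[mask].sum())
        use = mask & (total >= 2)
        if use.any():
            n_chrom = int(round(use.sum() / np.sum(1.0 / total[use])))
        else:
            n_chrom = 0
        theta_pi = pi_count / L if L > 0 else np.nan
        theta_w = (
            S / tajima_constants(n_chrom)["a1"] / L if (S > 0 and n_chrom >= 2 and L > 0) else 0.0
        )
        records.append({
            "feature_class": cls, "L": L, "S": S, "n_chrom": n_chrom,
            "theta_pi": theta_pi, "theta_w": theta_w,
            "tajima_d": tajima_d(pi_count, S, n_chrom) if n_chrom >= 2 else np.nan,
        })
    return pd.DataFrame(records)
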