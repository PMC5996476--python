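"""Selective-sweep and balancing-selection region calling.

Windows on the non-overlapping 10-kb grid are screened with joint
percentile criteria over the windowed statistics:

* sweep:      F_ST in the top 5% AND ROD > 0.5 AND Tajima's D in the
              bottom 10% of its distribution (D of the cultivated group);
* balancing:  F_ST in the bottom 5% AND Tajima's D in the top 5% AND θπ in
              the top 10%.

All criteria are conjunctive; a window missing any statistic never
qualifies.  Quantile cuts are computed genome-wide per comparison, with
ties at the cut value included.  Qualifying windows adjacent on the grid
are merged into maximal regions, which can then be annotated with the genes
they overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_KEY = ["chrom", "start", "end"]


@dataclass(frozen=True)
class SweepCriteria:
    fst_top_quantile: float = 0.05
    rod_min: float = 0.5
    tajd_bottom_quantile: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.fst_top_quantile < 1 and 0 < self.tajd_bottom_quantile < 1):
            raise ValueError("quantiles must lie in (0, 1)")
        if not 0 < self.rod_min <= 1:
            raise ValueError("rod_min must lie in (0, 1]")


@dataclass(frozen=True)
class BalancingCriteria:
    fst_bottom_quantile: float = 0.05
    tajd_top_quantile: float = 0.05
    theta_pi_top_quantile: float = 0.10

    def __post_init__(self) -> None:
        for q in (self.fst_bottom_quantile, self.tajd_top_quantile, self.theta_pi_top_quantile):
            if not 0 < q < 1:
                raise ValueError("quantiles must lie in (0, 1)")


@dataclass
class ScanResult:
    """Called regions plus the window-level detail behind them."""

    regions: pd.DataFrame          # chrom start end n_windows + summary stats
    window_mask: np.ndarray        # per grid window: did it qualify
    grid: pd.DataFrame             # the window grid the mask indexes
    thresholds: dict[str, float] = field(default_factory=dict)


def quantile_threshold(values, q: float, side: str) -> float:
    """Cut value such that the qualifying set has size ceil(q*N).

    ``side="top"`` qualifies the largest ceil(q*N) values (>= threshold),
    ``side="bottom"`` the smallest (<= threshold); ties at the threshold
    are included, and missing values are excluded from N.
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    v = np.asarray(values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("all values missing; no quantile threshold defined")
    k = int(np.ceil(q * v.size))
    k = min(max(k, 1), v.size)
    v.sort()
    return float(v[-k] if side == "top" else v[k - 1])


def _check_grid(*frames: pd.DataFrame) -> pd.DataFrame:
    ref = frames[0][GRID_KEY].reset_index(drop=True)
    for f in frames[1:]:
        if not f[GRID_KEY].reset_index(drop=True).equals(ref):
            raise ValueError("window grids of the input tables differ")
    starts = ref.groupby("chrom", sort=False)["start"]
    ends = ref.groupby("chrom", sort=False)["end"]
    if (starts.apply(lambda s: np.any(np.diff(s.to_numpy()) <= 0))).any():
        raise ValueError("grid windows not sorted within chromosome")
    # non-overlapping grid required for region merging
    for chrom, sub in ref.groupby("chrom", sort=False):
        if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
            raise ValueError("scan requires a non-overlapping window grid")
    return ref


def merge_windows(grid: pd.DataFrame, mask: np.ndarray,
                  stats: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Merge qualifying windows adjacent on the grid into maximal regions.

    ``stats`` maps output column names to (aggregator, per-window values)
    pairs; each aggregator is applied over the member windows of a region.
    """
    stats = stats or {}
    rows = []
    idx = np.flatnonzero(np.asarray(mask, dtype=bool))
    if idx.size == 0:
        cols = GRID_KEY + ["n_windows"] + list(stats)
        return pd.DataFrame(columns=cols)
    chroms = grid["chrom"].to_numpy()
    starts = grid["start"].to_numpy()
    ends = grid["end"].to_numpy()
    run = [idx[0]]
    runs = []
    for i in idx[1:]:
        prev = run[-1]
        if chroms[i] == chroms[prev] and starts[i] == ends[prev]:
            run.append(i)
        else:
            runs.append(run)
            run = [i]
    runs.append(run)
    for members in runs:
        members = np.array(members)
        row = {
            "chrom": chroms[members[0]],
            "start": int(starts[members[0]]),
            "end": int(ends[members[-1]]),
            "n_windows": len(members),
        }
        for name, (agg, vals) in stats.items():
            row[name] = agg(np.asarray(vals)[members])
        rows.append(row)
    return pd.DataFrame(rows)


def call_selective_sweeps(
    fst_windows: pd.DataFrame,
    rod_windows: pd.DataFrame,
    tajd_windows: pd.DataFrame,
    criteria: SweepCriteria = SweepCriteria(),
) -> ScanResult:
    """Call sweep regions from windowed F_ST, ROD and Tajima's D tables.

    ``tajd_windows`` is the diversity table of the group whose frequency
    spectrum the sweep is expected to have skewed — by default the
    cultivated member of the compared pair.
    """
    grid = _check_grid(fst_windows, rod_windows, tajd_windows)
    fst = fst_windows["fst"].to_numpy(dtype=np.float64)
    rod = rod_windows["rod"].to_numpy(dtype=np.float64)
    tajd = tajd_windows["tajima_d"].to_numpy(dtype=np.float64)
    fst_cut = quantile_threshold(fst, criteria.fst_top_quantile, "top")
    tajd_cut = quantile_threshold(tajd, criteria.tajd_bottom_quantile, "bottom")
    with np.errstate(invalid="ignore"):
        mask = (fst >= fst_cut) & (rod > criteria.rod_min) & (tajd <= tajd_cut)
    mask &= ~(np.isnan(fst) | np.isnan(rod) | np.isnan(tajd))
    regions = merge_windows(grid, mask, {
        "max_fst": (np.max, fst), "max_rod": (np.max, rod), "min_tajd": (np.min, tajd),
    })
    return ScanResult(regions=regions, window_mask=mask, grid=grid,
                      thresholds={"fst_cut": fst_cut, "tajd_cut": tajd_cut,
                                  "rod_min": criteria.rod_min})


def call_balancing_regions(
    fst_windows: pd.DataFrame,
    tajd_windows: pd.DataFrame,
    pi_windows: pd.DataFrame,
    criteria: BalancingCriteria = BalancingCriteria(),
) -> ScanResult:
    """Call balancing-selection regions (low F_ST, high D, high θπ)."""
    grid = _check_grid(fst_windows, tajd_windows, pi_windows)
    fst = fst_windows["fst"].to_numpy(dtype=np.float64)
    tajd = tajd_windows["tajima_d"].to_numpy(dtype=np.float64)
    pi = pi_windows["theta_pi"].to_numpy(dtype=np.float64)
    fst_cut = quantile_threshold(fst, criteria.fst_bottom_quantile, "bottom")
    tajd_cut = quantile_threshold(tajd, criteria.tajd_top_quantile, "top")
    pi_cut = quantile_threshold(pi, criteria.theta_pi_top_quantile, "top")
    with np.errstate(invalid="ignore"):
        mask = (fst <= fst_cut) & (tajd >= tajd_cut) & (pi >= pi_cut)
    mask &= ~(np.isnan(fst) | np.isnan(tajd) | np.isnan(pi))
    regions = merge_windows(grid, mask, {
        "min_fst": (np.min, fst), "max_tajd": (np.max, tajd), "max_theta_pi": (np.max, pi),
    })
    return ScanResult(regions=regions, window_mask=mask, grid=grid,
                      thresholds={"fst_cut": fst_cut, "tajd_cut": tajd_cut, "pi_cut": pi_cut})


def annotate_regions(regions: pd.DataFrame, gff: pd.DataFrame) -> pd.DataFrame:
    """Attach the IDs of genes overlapping each region by >= 1 bp.

    Regions are 0-based half-open; GFF3 genes are 1-based inclusive and are
    converted before the overlap test, so a gene starting exactly at a
    region's end coordinate does not count.
    """
    genes = gff[gff["type"] == "gene"]
    out = regions.copy()
    gene_lists = []
    for row in regions.itertuples():
        hits = genes[
            (genes["chrom"] == row.chrom)
            & (genes["start"] - 1 < row.end)
            & (genes["end"] > row.start)
        ]
        gene_lists.append(list(dict.fromkeys(hits["feature_id"])))
    out["gene_ids"] = gene_lists
    return out


def write_regions_bed(regions: pd.DataFrame, path, score_col: str | None = None) -> None:
    out = regions[GRID_KEY].copy()
    out["name"] = [f"region{i + 1}" for i in range(len(regions))]
    if score_col and score_col in regions:
        out["score"] = regions[score_col]
    out.to_csv(path, sep="\t", header=False, index=False)
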