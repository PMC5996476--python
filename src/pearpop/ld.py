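"""Linkage disequilibrium from unphased diploid genotypes.

Pairwise r² is computed from two-locus haplotype frequencies estimated by
expectation–maximization over unphased genotype pairs (only the double
heterozygote is phase-ambiguous), initialized at linkage equilibrium and
iterated to convergence — the standard treatment for genotype data.  Sites
enter the decay profile after the usual pre-filters: minor-allele frequency,
genotyping rate, and an exact Hardy–Weinberg test (defaults mirror common
practice for orchard-crop resequencing panels: distance cap 200 kb,
MAF >= 0.05, genotyping rate >= 0.6, HWE p >= 0.01).

The decay profile bins mean r² by inter-site distance — 100-bp bins over
the first 2 kb where LD in outcrossing pears collapses within hundreds of
bp, then 1-kb bins — and the half-decay distance is the midpoint of the
first bin whose mean r² has fallen to half the profile's maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrix import GenotypeMatrix


@dataclass(frozen=True)
class LDFilterConfig:
    max_distance: int = 200_000
    min_maf: float = 0.05
    min_genotyping_rate: float = 0.6
    hwe_p_cutoff: float = 0.01


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Given the allele counts, the probability of every feasible heterozygote
    configuration is computed and the p-value is the summed probability of
    configurations no more likely than the observed one.  Monomorphic sites
    return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    N = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # copies of the 'a' allele
    n_rare = min(n_a, 2 * N - n_a)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) % 2 == 0]
    hets = hets[hets <= n_rare]
    hom_rare = (n_rare - hets) // 2
    hom_common = N - hets - hom_rare
    hets = hets[hom_common >= 0]
    hom_rare = (n_rare - hets) // 2
    hom_common = N - hets - hom_rare
    # P(het) ∝ N! 2^het / (hom_rare! het! hom_common!)
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed_het = n_Aa
    p_obs = probs[np.flatnonzero(hets == observed_het)[0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


@dataclass
class LDPairRecord:
    """Two-locus LD estimate; haplotype order is (AB, Ab, aB, ab)."""

    pos1: int
    pos2: int
    distance: int
    hap_freqs: tuple[float, float, float, float]
    p_A: float
    p_B: float
    D: float
    d_prime: float
    r2: float
    n: int  # co-called samples
    missing: bool = False


def _em_batch(d1: np.ndarray, d2: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """Vectorized two-locus EM over unphased dosage columns.

    ``d1``/``d2`` have shape (n_samples, n_pairs) with -1 for missing.
    Returns per-pair haplotype frequencies (AB, Ab, aB, ab), allele
    frequencies, number of co-called samples, and a monomorphic flag.
    """
    both = (d1 >= 0) & (d2 >= 0)
    n_pairs = d1.shape[1]
    combo = np.where(both, d1 * 3 + d2, 9)
    counts = np.zeros((n_pairs, 10), dtype=np.float64)
    for k in range(10):
        counts[:, k] = (combo == k).sum(axis=0)
    n = both.sum(axis=0).astype(np.float64)
    c = counts[:, :9]  # index i*3+j for dosage (i, j)
    twoN = 2.0 * n
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (2 * (c[:, 6] + c[:, 7] + c[:, 8]) + c[:, 3] + c[:, 4] + c[:, 5]) / twoN
        pB = (2 * (c[:, 2] + c[:, 5] + c[:, 8]) + c[:, 1] + c[:, 4] + c[:, 7]) / twoN
    mono = ~np.isfinite(pA) | ~np.isfinite(pB) | (pA <= 0) | (pA >= 1) | (pB <= 0) | (pB >= 1)
    twoN = np.where(twoN > 0, twoN, 1.0)
    # monomorphic pairs get placeholder freqs so the vectorized loop converges
    pA = np.where(mono, 0.5, pA)
    pB = np.where(mono, 0.5, pB)

    n_dh = c[:, 4]  # double heterozygotes: the only ambiguous cell
    # unambiguous haplotype contributions
    base_AB = 2 * c[:, 8] + c[:, 7] + c[:, 5]
    base_Ab = 2 * c[:, 6] + c[:, 7] + c[:, 3]
    base_aB = 2 * c[:, 2] + c[:, 1] + c[:, 5]
    base_ab = 2 * c[:, 0] + c[:, 1] + c[:, 3]

    def run_em(pAB):
        pAb = pA - pAB
        paB = pB - pAB
        pab = 1 - pA - pB + pAB
        for _ in range(max_iter):
            denom = pAB * pab + pAb * paB
            w = np.where(denom > 0, pAB * pab / np.where(denom > 0, denom, 1.0), 0.5)
            with np.errstate(divide="ignore", invalid="ignore"):
                new_AB = (base_AB + n_dh * w) / twoN
                new_Ab = (base_Ab + n_dh * (1 - w)) / twoN
                new_aB = (base_aB + n_dh * (1 - w)) / twoN
                new_ab = (base_ab + n_dh * w) / twoN
            delta = np.max(
                np.abs(np.stack([new_AB - pAB, new_Ab - pAb, new_aB - paB, new_ab - pab])),
                initial=0.0,
            )
            pAB, pAb, paB, pab = new_AB, new_Ab, new_aB, new_ab
            if delta < tol:
                break
        return pAB, pAb, paB, pab

    def loglik(freqs):
        pAB, pAb, paB, pab = (np.maximum(f, 1e-300) for f in freqs)
        cell = [
            pab**2, 2 * pab * paB, paB**2,
            2 * pab * pAb, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB,
            pAb**2, 2 * pAB * pAb, pAB**2,
        ]
        return sum(c[:, k] * np.log(np.maximum(cell[k], 1e-300)) for k in range(9))

    # the observed-data likelihood can be bimodal in D; run EM from the
    # equilibrium start and from both Fréchet extremes, keep the best
    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    eps = 0.05 * (hi - lo)
    best = None
    best_ll = np.full(n_pairs, -np.inf)
    for start in (pA * pB, lo + eps, hi - eps):
        freqs = run_em(start.copy())
        ll = loglik(freqs)
        if best is None:
            best = [f.copy() for f in freqs]
            best_ll = ll
        else:
            better = ll > best_ll + 1e-12
            for k in range(4):
                best[k] = np.where(better, freqs[k], best[k])
            best_ll = np.where(better, ll, best_ll)
    pAB, pAb, paB, pab = best
    return pAB, pAb, paB, pab, pA, pB, n, mono


def _r2_from_freqs(pAB, pA, pB):
    D = pAB - pA * pB
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
        dmax = np.where(D >= 0, np.minimum(pA * (1 - pB), (1 - pA) * pB),
                        np.minimum(pA * pB, (1 - pA) * (1 - pB)))
        d_prime = np.where(dmax > 0, np.abs(D) / dmax, np.nan)
    return D, d_prime, r2


def pair_r2(geno1: np.ndarray, geno2: np.ndarray,
            pos1: int = 0, pos2: int = 0, return_trace: bool = False):
    """EM-based r² between two dosage vectors (pairwise deletion).

    With ``return_trace=True`` also returns the per-iteration observed-data
    log-likelihood, which is non-decreasing under EM.
    """
    d1 = np.asarray(geno1, dtype=np.int64).reshape(-1, 1)
    d2 = np.asarray(geno2, dtype=np.int64).reshape(-1, 1)
    trace: list[float] = []
    if return_trace:
        _em_traced(d1[:, 0], d2[:, 0], trace)
    pAB, pAb, paB, pab, pA, pB, n, mono = _em_batch(d1, d2)
    D, d_prime, r2 = _r2_from_freqs(pAB, pA, pB)
    if mono[0]:
        rec = LDPairRecord(
            pos1=pos1, pos2=pos2, distance=abs(pos2 - pos1),
            hap_freqs=(np.nan,) * 4, p_A=np.nan, p_B=np.nan, D=np.nan,
            d_prime=np.nan, r2=np.nan, n=int(n[0]), missing=True,
        )
    else:
        rec = LDPairRecord(
            pos1=pos1, pos2=pos2, distance=abs(pos2 - pos1),
            hap_freqs=(float(pAB[0]), float(pAb[0]), float(paB[0]), float(pab[0])),
            p_A=float(pA[0]), p_B=float(pB[0]), D=float(D[0]),
            d_prime=float(d_prime[0]), r2=float(r2[0]),
            n=int(n[0]), missing=False,
        )
    return (rec, trace) if return_trace else rec


def _genotype_probs(pAB, pAb, paB, pab):
    """3x3 genotype-pair probabilities under random union of haplotypes."""
    P = np.zeros((3, 3))
    P[0, 0] = pab**2
    P[0, 1] = 2 * pab * paB
    P[0, 2] = paB**2
    P[1, 0] = 2 * pab * pAb
    P[1, 1] = 2 * (pAB * pab + pAb * paB)
    P[1, 2] = 2 * pAB * paB
    P[2, 0] = pAb**2
    P[2, 1] = 2 * pAB * pAb
    P[2, 2] = pAB**2
    return P


def _em_traced(d1, d2, trace: list[float], max_iter: int = 1000, tol: float = 1e-10):
    both = (d1 >= 0) & (d2 >= 0)
    d1, d2 = d1[both], d2[both]
    counts = np.zeros((3, 3))
    for a, b in zip(d1, d2):
        counts[a, b] += 1
    n = counts.sum()
    if n == 0:
        return
    pA = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    pAB, pAb, paB, pab = pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)
    for _ in range(max_iter):
        P = _genotype_probs(pAB, pAb, paB, pab)
        with np.errstate(divide="ignore"):
            ll = float(np.sum(counts * np.where(counts > 0, np.log(np.maximum(P, 1e-300)), 0.0)))
        trace.append(ll)
        denom = pAB * pab + pAb * paB
        w = pAB * pab / denom if denom > 0 else 0.5
        ndh = counts[1, 1]
        new = np.array([
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + ndh * w,
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + ndh * (1 - w),
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + ndh * (1 - w),
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + ndh * w,
        ]) / (2 * n)
        if np.max(np.abs(new - np.array([pAB, pAb, paB, pab]))) < tol:
            pAB, pAb, paB, pab = new
            break
        pAB, pAb, paB, pab = new


def default_bin_edges(max_distance: int) -> np.ndarray:
    """100-bp bins up to 2 kb, then 1-kb bins out to the distance cap."""
    fine = np.arange(0, min(2000, max_distance) + 1, 100)
    coarse = np.arange(3000, max_distance + 1, 1000)
    return np.unique(np.concatenate([fine, coarse, [max_distance]]))


def eligible_sites(matrix: GenotypeMatrix, rows: np.ndarray,
                   filters: LDFilterConfig) -> np.ndarray:
    """Site indices passing the MAF / genotyping-rate / HWE pre-filters."""
    d = matrix.dosages[rows]
    called = d >= 0
    n_called = called.sum(axis=0)
    geno_rate = n_called / rows.size
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2 * n_called)
    maf = np.minimum(p, 1 - p)
    keep = (geno_rate >= filters.min_genotyping_rate) & (maf >= filters.min_maf)
    keep &= n_called > 0
    idx = np.flatnonzero(keep)
    hwe_ok = np.ones(idx.size, dtype=bool)
    for k, s in enumerate(idx):
        col = d[:, s]
        hwe_ok[k] = hwe_exact_test(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        ) >= filters.hwe_p_cutoff
    return idx[hwe_ok]


def ld_decay_profile(
    matrix: GenotypeMatrix,
    group: str,
    filters: LDFilterConfig = LDFilterConfig(),
    bin_edges: np.ndarray | None = None,
    max_sites_per_chrom: int | None = 2000,
    exclude_species: tuple[str, ...] = (),
    batch_size: int = 50_000,
) -> pd.DataFrame:
    """Mean r² per distance bin over all eligible within-chromosome pairs.

    ``max_sites_per_chrom`` thins eligible sites to an evenly spaced subset
    (deterministic) to keep the pair count tractable; set None to disable.
    Returns ``bin_start bin_end mean_r2 n_pairs`` rows, empty if no pair.
    """
    rows = matrix.group_indices(group, exclude_species)
    if rows.size < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples")
    edges = default_bin_edges(filters.max_distance) if bin_edges is None else np.asarray(bin_edges)
    sums = np.zeros(len(edges) - 1)
    npair = np.zeros(len(edges) - 1, dtype=np.int64)

    for chrom in matrix.chroms:
        sel = matrix.site_selector(chrom)
        local = eligible_sites(matrix.take_sites(sel), rows, filters)
        if max_sites_per_chrom is not None and local.size > max_sites_per_chrom:
            pick = np.unique(np.linspace(0, local.size - 1, max_sites_per_chrom).astype(int))
            local = local[pick]
        sites = sel[local]
        pos = matrix.sites["pos"].to_numpy()[sites]
        if sites.size < 2:
            continue
        # enumerate pairs within the distance cap
        hi = np.searchsorted(pos, pos + filters.max_distance, side="right")
        i_idx = np.concatenate([
            np.full(hi[i] - i - 1, i, dtype=np.int64) for i in range(sites.size)
        ]) if sites.size else np.empty(0, dtype=np.int64)
        j_idx = np.concatenate([
            np.arange(i + 1, hi[i], dtype=np.int64) for i in range(sites.size)
        ]) if sites.size else np.empty(0, dtype=np.int64)
        for b0 in range(0, i_idx.size, batch_size):
            bi = i_idx[b0: b0 + batch_size]
            bj = j_idx[b0: b0 + batch_size]
            d1 = matrix.dosages[np.ix_(rows, sites[bi])].astype(np.int64)
            d2 = matrix.dosages[np.ix_(rows, sites[bj])].astype(np.int64)
            pAB, _, _, _, pA, pB, _, mono = _em_batch(d1, d2)
            _, _, r2 = _r2_from_freqs(pAB, pA, pB)
            dist = pos[bj] - pos[bi]
            ok = ~mono & ~np.isnan(r2)
            which = np.digitize(dist[ok], edges) - 1
            valid = (which >= 0) & (which < len(edges) - 1)
            np.add.at(sums, which[valid], r2[ok][valid])
            np.add.at(npair, which[valid], 1)
    out = pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:],
        "mean_r2": np.where(npair > 0, sums / np.maximum(npair, 1), np.nan),
        "n_pairs": npair,
    })
    return out[out["n_pairs"] > 0].reset_index(drop=True)


def half_decay_distance(profile: pd.DataFrame) -> float:
    """Distance at which binned mean r² first falls to half its maximum.

    The maximum is the global maximum of the binned means; the scan runs
    left to right and returns the midpoint of the first bin at or below
    half-maximum, or NaN if the profile never decays that far.
    """
    if len(profile) == 0:
        raise ValueError("empty LD profile")
    means = profile["mean_r2"].to_numpy(dtype=np.float64)
    peak = np.nanmax(means)
    below = np.flatnonzero(means <= 0.5 * peak)
    if below.size == 0:
        return np.nan
    row = profile.iloc[below[0]]
    return float((row["bin_start"] + row["bin_end"]) / 2.0)
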